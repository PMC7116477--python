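"""Segment-averaged tapered cross-spectral estimation and coherence.

The estimator divides each record into disjoint segments of ``seg_len``
samples (default 2**8, ~1.3 s at 200 Hz), removes the per-segment mean,
applies a Hann taper with power normalization, and averages the one-sided
cross-periodograms over segments.  Coherence is the magnitude-squared
normalized cross-spectrum

    |R_yx(w)|^2 = |f_yx(w)|^2 / (f_xx(w) f_yy(w))  in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .mvar import TimeSeriesData

__all__ = ["SpectralMatrix", "spectral_matrix", "coherence"]


@dataclass(frozen=True)
class SpectralMatrix:
    """Frequency-resolved N x N cross-spectral density.

    ``values[k]`` is the Hermitian CSD matrix at ``freqs[k]``; the one-sided
    grid runs from 0 to Nyquist at spacing fs/seg_len.
    """

    freqs: np.ndarray
    values: np.ndarray  # (F, N, N) complex
    n_segments: int
    seg_len: int
    fs: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.freqs.shape[0]

    def autospectrum(self, i: int) -> np.ndarray:
        return self.values[:, i, i].real

    def submatrix(self, channels) -> "SpectralMatrix":
        idx = np.asarray(channels, dtype=int)
        return SpectralMatrix(
            freqs=self.freqs,
            values=self.values[np.ix_(np.arange(self.n_freqs), idx, idx)],
            n_segments=self.n_segments,
            seg_len=self.seg_len,
            fs=self.fs,
        )


def _segment_ffts(data: np.ndarray, seg_len: int, window: np.ndarray) -> np.ndarray:
    """Windowed rFFTs of disjoint, per-segment-demeaned segments: (n_seg, N, F)."""
    n, t = data.shape
    n_seg = t // seg_len
    segs = data[:, : n_seg * seg_len].reshape(n, n_seg, seg_len)
    segs = segs - segs.mean(axis=2, keepdims=True)
    tapered = segs * window[None, None, :]
    return np.fft.rfft(tapered, axis=2).transpose(1, 0, 2)


def spectral_matrix(
    x: TimeSeriesData | list[TimeSeriesData],
    seg_len: int = 256,
    window: str = "hann",
) -> SpectralMatrix:
    """Estimate the cross-spectral density matrix by disjoint-segment averaging.

    Accepts a single record or a list of records (epochs/trials); each record
    contributes ``floor(T / seg_len)`` disjoint segments.  Raises if fewer
    than two segments are available in total.
    """
    records = x if isinstance(x, (list, tuple)) else [x]
    fs = records[0].fs
    n = records[0].n_channels
    for rec in records:
        if rec.fs != fs or rec.n_channels != n:
            raise ValueError("all records must share fs and channel count")
    if seg_len & (seg_len - 1) != 0:
        warnings.warn(f"seg_len={seg_len} is not a power of two", stacklevel=2)
    win = get_window(window, seg_len, fftbins=True)
    ffts = [
        _segment_ffts(rec.data, seg_len, win)
        for rec in records
        if rec.n_samples >= seg_len
    ]
    if not ffts:
        raise ValueError(f"no record is at least seg_len={seg_len} samples long")
    coeffs = np.concatenate(ffts, axis=0)  # (n_seg, N, F)
    n_seg = coeffs.shape[0]
    if n_seg < 2:
        raise ValueError(f"need at least 2 segments, got {n_seg}")
    # One-sided density normalization: 2 / (fs * sum(w^2)), halved at DC/Nyquist.
    scale = 2.0 / (fs * np.sum(win**2))
    s = np.einsum("sif,sjf->fij", coeffs, np.conj(coeffs)) * (scale / n_seg)
    s[0] *= 0.5
    if seg_len % 2 == 0:
        s[-1] *= 0.5
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return SpectralMatrix(freqs=freqs, values=s, n_segments=n_seg, seg_len=seg_len, fs=fs)


def coherence(s: SpectralMatrix, i: int, j: int) -> np.ndarray:
    """Magnitude-squared coherence spectrum between channels ``i`` and ``j``.

    Frequencies where either autospectrum vanishes yield NaN (flagged
    undefined), never 0.
    """
    if i == j:
        raise ValueError("coherence requires two distinct channels")
    sii = s.values[:, i, i].real
    sjj = s.values[:, j, j].real
    denom = sii * sjj
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s.values[:, j, i]) ** 2 / denom
    coh = np.where(denom > 0, coh, np.nan)
    return np.clip(coh, 0.0, 1.0, out=coh)
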