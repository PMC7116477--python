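"""Non-parametric directionality (NPD).

NPD decomposes the coherence between two channels into reverse-lagged,
zero-lag and forward-lagged components.  The spectral matrix is MMSE
pre-whitened (unit autospectra, off-diagonal magnitude-squared equal to the
coherence); the whitened cross-spectrum is transformed to the lag domain to
give a correlation sequence rho(tau); the tau < 0, tau = 0 and tau > 0 parts
are transformed back to frequency and rescaled at each frequency so that the
three component spectra sum exactly to the coherence.  The scalar dependence
R^2 splits correspondingly into R^2_-, R^2_0 and R^2_+ (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import SpectralMatrix, coherence

__all__ = [
    "WhitenedSpectralMatrix",
    "NPDResult",
    "prewhiten",
    "lag_correlation",
    "npd_decompose",
]


@dataclass(frozen=True)
class WhitenedSpectralMatrix:
    """MMSE pre-whitened spectral matrix: unit diagonal at every frequency."""

    freqs: np.ndarray
    values: np.ndarray  # (F, N, N) complex
    seg_len: int
    fs: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NPDResult:
    """Coherence and its three directional components for an ordered pair.

    ``forward`` carries correlations in which the source leads the target
    (i -> j), ``reverse`` those in which the target leads, ``zero`` the
    instantaneous part.  ``forward + reverse + zero == coherence`` at every
    frequency.  ``scalar_*`` are the lag-domain (Parseval) components of the
    overall squared dependence; ``rho`` is the whitened lag correlation at
    lags ``lags``.  ``raw_*`` retain the component spectra before the
    per-frequency renormalization.
    """

    freqs: np.ndarray
    coherence: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray
    zero: np.ndarray
    scalar_forward: float
    scalar_reverse: float
    scalar_zero: float
    lags: np.ndarray
    rho: np.ndarray
    raw_forward: np.ndarray
    raw_reverse: np.ndarray
    raw_zero: np.ndarray
    n_undefined: int = 0

    @property
    def scalar_total(self) -> float:
        return self.scalar_forward + self.scalar_reverse + self.scalar_zero


def prewhiten(s: SpectralMatrix) -> WhitenedSpectralMatrix:
    """MMSE pre-whitening: Fw_ij = S_ij / sqrt(S_ii S_jj); unit diagonal."""
    auto = np.real(np.einsum("fii->fi", s.values))
    bad = auto <= 0
    if np.any(bad):
        k, i = np.argwhere(bad)[0]
        raise ValueError(
            f"autospectrum of channel {i} vanishes at {s.freqs[k]:.3f} Hz; "
            "cannot pre-whiten"
        )
    scale = 1.0 / np.sqrt(auto)
    fw = s.values * scale[:, :, None] * scale[:, None, :]
    return WhitenedSpectralMatrix(freqs=s.freqs, values=fw, seg_len=s.seg_len, fs=s.fs)


def _two_sided(one_sided: np.ndarray, seg_len: int) -> np.ndarray:
    """Hermitian extension of a one-sided cross-spectrum onto the full FFT grid."""
    full = np.empty(seg_len, dtype=complex)
    m = seg_len // 2
    full[: m + 1] = one_sided
    full[m + 1:] = np.conj(one_sided[1:m][::-1])
    return full


def lag_correlation(
    fw: WhitenedSpectralMatrix, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Whitened lag-correlation sequence rho(tau) for the ordered pair (i, j).

    rho is the inverse transform of the whitened cross-spectrum f^w_{ji};
    positive lags correspond to channel ``i`` leading channel ``j``.  Returns
    ``(lags, rho)`` with lags running from ``-(seg_len/2 - 1)`` to
    ``+seg_len/2``.  By Parseval, ``sum(rho**2)`` equals the mean coherence
    over the full two-sided grid.
    """
    seg_len = fw.seg_len
    m = seg_len // 2
    full = _two_sided(fw.values[:, j, i], seg_len)
    rho_raw = np.fft.ifft(full)
    # index 0..m -> lags 0..m; index m+1..L-1 -> lags -(m-1)..-1
    rho = np.real(np.roll(rho_raw, m - 1))
    lags = np.arange(-(m - 1), m + 1)
    return lags, rho


def npd_decompose(s: SpectralMatrix, i: int, j: int) -> NPDResult:
    """Decompose the coherence of the ordered pair (i, j) by time lag.

    Returns spectra on the one-sided grid of ``s``.  Frequencies where the
    coherence is numerically zero get all three components set to zero.
    """
    if i == j:
        raise ValueError("npd_decompose requires two distinct channels")
    fw = prewhiten(s)
    seg_len = s.seg_len
    m = seg_len // 2
    full = _two_sided(fw.values[:, j, i], seg_len)
    rho = np.real(np.fft.ifft(full))  # natural FFT order: lag 0..m, then -(m-1)..-1

    # Amplitude weights per lag bin.  The single tau=0 bin carries the
    # instantaneous component; the ambiguous lag-m bin (the "Nyquist lag" of
    # the circular grid, where +m and -m coincide) is split evenly between
    # forward and reverse so that direction labels swap exactly under
    # argument exchange while the lag-domain Parseval sum stays exact.
    weights = {
        "zero": np.zeros(seg_len),
        "forward": np.zeros(seg_len),
        "reverse": np.zeros(seg_len),
    }
    weights["zero"][0] = 1.0
    weights["forward"][1:m] = 1.0        # tau > 0: source leads target
    weights["reverse"][m + 1:] = 1.0     # tau < 0
    half = np.sqrt(0.5)
    weights["forward"][m] = half
    weights["reverse"][m] = half

    raw = {}
    scalars = {}
    for name, w in weights.items():
        comp = w * rho
        spec = np.fft.fft(comp)[: m + 1]
        raw[name] = np.abs(spec) ** 2
        scalars[name] = float(np.sum(comp**2))

    coh = coherence(s, i, j)
    undefined = np.isnan(coh)
    coh = np.where(undefined, 0.0, coh)
    total = raw["forward"] + raw["reverse"] + raw["zero"]
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = coh / total
    scale = np.where((total > 0) & (coh > 0), scale, 0.0)

    lags = np.arange(-(m - 1), m + 1)
    return NPDResult(
        freqs=s.freqs,
        coherence=coh,
        forward=raw["forward"] * scale,
        reverse=raw["reverse"] * scale,
        zero=raw["zero"] * scale,
        scalar_forward=scalars["forward"],
        scalar_reverse=scalars["reverse"],
        scalar_zero=scalars["zero"],
        lags=lags,
        rho=np.roll(rho, m - 1),
        raw_forward=raw["forward"],
        raw_reverse=raw["reverse"],
        raw_zero=raw["zero"],
        n_undefined=int(np.sum(undefined)),
    )
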