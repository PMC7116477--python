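"""Conditioned (partialized) NPD.

Partializing the spectral matrix on a reference channel Z removes the linear
contribution of Z from every remaining auto- and cross-spectrum:

    f_ab|z(w) = f_ab(w) - f_az(w) f_zb(w) / f_zz(w)

The NPD pipeline applied to the partialized matrix decomposes the *partial*
coherence into the same forward / reverse / zero-lag components, which is the
conditioned NPD, written NPD(Z).  If Z fully mediates the dependence between
two channels (serial routing X -> Z -> Y) the partial coherence, and hence
every component, vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .npd import NPDResult, npd_decompose
from .spectral import SpectralMatrix

__all__ = ["ConditionedSpectralMatrix", "partialize", "conditioned_npd"]


@dataclass(frozen=True)
class ConditionedSpectralMatrix:
    """Spectral matrix of the remaining channels after partializing on ``ref``.

    ``channels`` maps rows of the partial matrix back to the original channel
    indices.
    """

    spectral: SpectralMatrix
    ref_channel: int
    channels: tuple[int, ...]

    def index_of(self, original_channel: int) -> int:
        try:
            return self.channels.index(original_channel)
        except ValueError:
            raise ValueError(
                f"channel {original_channel} is not in the partialized matrix "
                f"(reference was {self.ref_channel})"
            ) from None


def partialize(s: SpectralMatrix, ref: int) -> ConditionedSpectralMatrix:
    """Partial spectral matrix given a single reference channel."""
    n = s.n_channels
    if n < 3:
        raise ValueError("partialization needs at least 3 channels")
    if not (0 <= ref < n):
        raise ValueError(f"reference channel {ref} out of range")
    szz = s.values[:, ref, ref].real
    if np.any(szz <= 0):
        k = int(np.argmax(szz <= 0))
        raise ValueError(
            f"reference autospectrum vanishes at {s.freqs[k]:.3f} Hz; cannot partialize"
        )
    keep = tuple(i for i in range(n) if i != ref)
    idx = np.asarray(keep)
    saz = s.values[:, idx, ref]  # (F, N-1)
    szb = s.values[:, ref, idx]  # (F, N-1)
    sub = s.values[np.ix_(np.arange(s.n_freqs), idx, idx)]
    partial = sub - saz[:, :, None] * szb[:, None, :] / szz[:, None, None]
    # numerical guard: keep the diagonal real and non-negative
    diag = np.einsum("fii->fi", partial)
    diag[...] = np.maximum(diag.real, 0.0)
    out = SpectralMatrix(
        freqs=s.freqs,
        values=partial,
        n_segments=s.n_segments,
        seg_len=s.seg_len,
        fs=s.fs,
    )
    return ConditionedSpectralMatrix(spectral=out, ref_channel=ref, channels=keep)


def conditioned_npd(s: SpectralMatrix, i: int, j: int, ref: int) -> NPDResult:
    """NPD of the ordered pair (i, j) conditioned on channel ``ref`` (NPD(ref)).

    The three components sum to the partial coherence |R_ji|ref(w)|^2 at
    every frequency.
    """
    if len({i, j, ref}) != 3:
        raise ValueError("i, j and ref must be three distinct channels")
    cond = partialize(s, ref)
    return npd_decompose(cond.spectral, cond.index_of(i), cond.index_of(j))
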