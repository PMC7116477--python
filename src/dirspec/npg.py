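"""Non-parametric Granger causality (NPG) via Wilson spectral factorization.

The spectral matrix S(w) is factorized as S = H Sigma H* with H minimum
phase (H(lag 0) = I) and Sigma the innovation covariance, using Wilson's
iterative algorithm.  Geweke's frequency-domain Granger causality then
decomposes the total power of a target channel into an intrinsic part and a
causal contribution from the source:

    F_{x->y}(w) = ln[ S_yy(w) / (S_yy(w) - (Sig_xx - Sig_yx^2/Sig_yy) |H_yx(w)|^2) ]

``pairwise_npg`` factorizes the 2x2 submatrix of each pair; ``multivariate_npg``
factorizes the full channel set once and applies the same formula with the
full-system transfer function and noise covariance, so that influences routed
through the remaining channels are absorbed into the full-system H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky

from .spectral import SpectralMatrix

__all__ = [
    "FactorizationResult",
    "NPGResult",
    "wilson_factorize",
    "pairwise_npg",
    "multivariate_npg",
]


@dataclass(frozen=True)
class FactorizationResult:
    """Minimum-phase spectral factor: S(w) = H(w) Sigma H(w)* on the one-sided grid."""

    freqs: np.ndarray
    transfer: np.ndarray  # (F, N, N) complex, H with H(lag0) = I
    noise_cov: np.ndarray  # (N, N) real
    n_iterations: int
    residual: float


@dataclass(frozen=True)
class NPGResult:
    """Directional Granger spectra per ordered pair.

    ``granger[(i, j)]`` is the causal spectrum i -> j; ``instantaneous[(i, j)]``
    (unordered, stored with i < j) the instantaneous term, reported unclipped
    (it can be negative in confounded data).  ``n_clipped`` counts negative
    directional values clipped to zero.
    """

    freqs: np.ndarray
    granger: dict
    instantaneous: dict
    n_clipped: int


def _plus_operator(g: np.ndarray, m: int) -> np.ndarray:
    """Causal (non-negative lag) part of g on the full FFT grid (F axis first)."""
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    # keep the upper triangle (incl. diagonal) of the halved zero-lag term
    beta0 = np.triu(beta0)
    gam[0] = beta0
    gam[m + 1:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    s: SpectralMatrix,
    tol: float = 1e-9,
    max_iter: int = 500,
    recon_tol: float = 1e-1,
    diagonal_loading: bool = False,
) -> FactorizationResult:
    """Wilson's iterative spectral matrix factorization.

    Initialized with the Cholesky factor of the zero-lag covariance; iterates
    psi <- psi . plus(psi^-1 S psi^-* + I) until the maximum relative change
    of psi falls below ``tol`` (or ``max_iter`` sweeps).  The causal factor
    lives on seg_len/2 + 1 lags, so an estimated spectrum with very sharp
    resonances carries a small irreducible reconstruction error; the run is
    accepted when the worst-frequency relative Frobenius residual of
    H Sigma H* against S is below ``recon_tol``, and the residual is always
    reported on the result.  Raises on residuals beyond ``recon_tol`` (with
    iteration count and final residual) and on rank-deficient input.
    """
    seg_len = s.seg_len
    m = seg_len // 2
    n = s.n_channels
    values = s.values
    if diagonal_loading:
        eps = 1e-8 * np.real(np.trace(values.mean(axis=0))) / n
        values = values + eps * np.eye(n)[None, :, :]
        warnings.warn("diagonal loading applied to the spectral matrix", stacklevel=2)
    # balance per-channel power so widely different channel scales (e.g. a
    # noise-dominated channel) do not destabilize the iteration; undone below
    power = np.real(np.einsum("fii->i", values)) / values.shape[0]
    if np.any(power <= 0):
        raise ValueError("every channel needs positive mean power to factorize")
    d_sqrt = np.sqrt(power)
    values = values / (d_sqrt[None, :, None] * d_sqrt[None, None, :])
    # two-sided Hermitian extension, frequency axis length seg_len
    sf = np.empty((seg_len, n, n), dtype=complex)
    sf[: m + 1] = values
    # S(-w) = conj(S(w)) elementwise (= S(w)^T for Hermitian matrices)
    sf[m + 1:] = np.conj(values[1:m][::-1])

    gam = np.real(np.fft.ifft(sf, axis=0))
    gam0 = gam[0]
    try:
        h0 = cholesky(gam0, lower=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "zero-lag covariance is not positive definite; the spectral matrix "
            "may be rank deficient - consider diagonal_loading=True"
        ) from exc
    psi = np.broadcast_to(h0.astype(complex), (seg_len, n, n)).copy()

    eye = np.eye(n)
    den = np.linalg.norm(sf, axis=(1, 2))

    def _residual(p):
        recon = p @ np.conj(np.swapaxes(p, 1, 2))
        num = np.linalg.norm(recon - sf, axis=(1, 2))
        return float(np.max(num / np.maximum(den, 1e-300)))

    # On near-singular input the iteration can enter a slow limit cycle after
    # reaching its accuracy floor; keep the best factor seen so far.
    best_psi, best_residual, best_it = psi.copy(), _residual(psi), 0
    it = 0
    for it in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ sf @ np.conj(np.swapaxes(psi_inv, 1, 2)) + eye
        gp = _plus_operator(g, m)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if it % 10 == 0 or delta < tol or it == max_iter:
            res = _residual(psi)
            if res < best_residual:
                best_psi, best_residual, best_it = psi.copy(), res, it
        if delta < tol:
            break
    psi = best_psi

    a0 = np.real(np.fft.ifft(psi, axis=0)[0])
    transfer_full = psi @ np.linalg.inv(a0)
    sigma = a0 @ a0.T
    it = best_it
    # undo the power balancing: H -> D^1/2 H D^-1/2 keeps H(lag 0) = I
    transfer_full = transfer_full * (d_sqrt[None, :, None] / d_sqrt[None, None, :])
    sigma = sigma * np.outer(d_sqrt, d_sqrt)
    # report the residual of the returned reconstruction on the input scale
    sf_orig = sf * (d_sqrt[None, :, None] * d_sqrt[None, None, :])
    recon = transfer_full @ sigma @ np.conj(np.swapaxes(transfer_full, 1, 2))
    num = np.linalg.norm(recon - sf_orig, axis=(1, 2))
    den_orig = np.linalg.norm(sf_orig, axis=(1, 2))
    residual = float(np.max(num / np.maximum(den_orig, 1e-300)))

    if residual > recon_tol:
        raise RuntimeError(
            f"Wilson factorization failed after {it} iterations "
            f"(relative reconstruction residual {residual:.3e} > {recon_tol:.1e}); "
            "the spectral matrix may be near-singular - consider diagonal_loading=True"
        )
    return FactorizationResult(
        freqs=s.freqs,
        transfer=transfer_full[: m + 1],
        noise_cov=sigma,
        n_iterations=it,
        residual=residual,
    )


def _geweke_pair(
    h: np.ndarray, sigma: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, int]:
    """Geweke causal spectrum i -> j from transfer h (F,N,N) and noise cov sigma."""
    recon = h @ sigma @ np.conj(np.swapaxes(h, 1, 2))
    s_jj = recon[:, j, j].real
    sig_partial = sigma[i, i] - sigma[j, i] ** 2 / sigma[j, j]
    intrinsic = s_jj - sig_partial * np.abs(h[:, j, i]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.log(s_jj / intrinsic)
    f = np.where((s_jj > 0) & (intrinsic > 0), f, np.inf)
    f = np.where(np.isfinite(f), f, np.nan)
    n_clipped = int(np.sum(f < 0))
    return np.clip(f, 0.0, None), n_clipped


def _instantaneous(h: np.ndarray, sigma: np.ndarray, i: int, j: int) -> np.ndarray:
    """Instantaneous causality spectrum: total interdependence minus both directions."""
    sub = np.ix_([i, j], [i, j])
    recon = h @ sigma @ np.conj(np.swapaxes(h, 1, 2))
    s2 = recon[(slice(None),) + sub]
    det = np.real(s2[:, 0, 0] * s2[:, 1, 1] - s2[:, 0, 1] * s2[:, 1, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.log(s2[:, 0, 0].real * s2[:, 1, 1].real / det)
    fij, _ = _geweke_pair(h, sigma, i, j)
    fji, _ = _geweke_pair(h, sigma, j, i)
    return total - fij - fji


def pairwise_npg(s: SpectralMatrix, i: int, j: int, **factor_kw) -> NPGResult:
    """Pairwise NPG for the ordered pair (i, j): factorizes the 2x2 submatrix.

    Returns both directions and the (unclipped) instantaneous spectrum.
    """
    if i == j:
        raise ValueError("pairwise_npg requires two distinct channels")
    sub = s.submatrix([i, j])
    fac = wilson_factorize(sub, **factor_kw)
    fwd, c1 = _geweke_pair(fac.transfer, fac.noise_cov, 0, 1)
    rev, c2 = _geweke_pair(fac.transfer, fac.noise_cov, 1, 0)
    inst = _instantaneous(fac.transfer, fac.noise_cov, 0, 1)
    return NPGResult(
        freqs=s.freqs,
        granger={(i, j): fwd, (j, i): rev},
        instantaneous={(min(i, j), max(i, j)): inst if i < j else inst},
        n_clipped=c1 + c2,
    )


def multivariate_npg(s: SpectralMatrix, **factor_kw) -> NPGResult:
    """Multivariate NPG: one full-matrix factorization, all ordered pairs.

    The full-system transfer function carries only the direct and relayed
    linear routes between channels, so influences that a pairwise analysis
    attributes to a spurious edge (e.g. lagged common drive) are absorbed by
    the full factorization.  For N = 2 this coincides with ``pairwise_npg``.
    """
    fac = wilson_factorize(s, **factor_kw)
    n = s.n_channels
    granger = {}
    inst = {}
    n_clipped = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            f, c = _geweke_pair(fac.transfer, fac.noise_cov, i, j)
            granger[(i, j)] = f
            n_clipped += c
            if i < j:
                inst[(i, j)] = _instantaneous(fac.transfer, fac.noise_cov, i, j)
    return NPGResult(freqs=s.freqs, granger=granger, instantaneous=inst, n_clipped=n_clipped)
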