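"""Confound sweeps and logistic calibration curves.

Each sweep simulates a fixed MVAR model, injects one confound (symmetric
SNR, SNR asymmetry, instantaneous mixing, or reference-channel SNR) over a
grid, estimates connectivity with coherence / NPD / NPG, and records the
peak value of each estimate over the frequency grid (DC excluded).
Sigmoidal responses are summarized with a least-squares logistic fit
y = A / (1 + exp(-kappa (x - x0))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .conditioned import conditioned_npd
from .mvar import DirectedGraph, MVARModel, TimeSeriesData, build_periodic_model, simulate
from .npd import npd_decompose
from .npg import multivariate_npg, pairwise_npg
from .observation import ObservationSpec, lambda_for_snr, mixing_matrix, observe
from .spectral import coherence, spectral_matrix
from .surrogates import phase_randomize

__all__ = [
    "LogisticFit",
    "SweepResult",
    "peak",
    "sweep_snr",
    "sweep_delta_snr",
    "sweep_mixing",
    "sweep_conditioning_snr",
    "fit_logistic",
    "ARCHITECTURES",
]

#: Three-node topologies used for the conditioning sweeps (node 0 = X,
#: node 1 = Y, node 2 = Z; edges at equal lag and coupling).
ARCHITECTURES = {
    "serial": ((0, 2, 2), (2, 1, 2)),          # X -> Z -> Y
    "feedforward": ((0, 1, 2), (1, 2, 2)),     # X -> Y -> Z
    "recurrent": ((0, 1, 2), (1, 2, 2), (2, 0, 2)),  # X -> Y -> Z -> X
}


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic fit y = A / (1 + exp(-kappa (x - x0)))."""

    maximum: float
    midpoint: float
    steepness: float
    r_squared: float

    @property
    def reliable(self) -> bool:
        """Fits are reported as summary statistics only when R^2 > 0.95."""
        return self.r_squared > 0.95

    def __call__(self, x):
        return self.maximum / (1.0 + np.exp(-self.steepness * (np.asarray(x) - self.midpoint)))


@dataclass(frozen=True)
class SweepResult:
    """Long-format record of one confound sweep."""

    confound_name: str
    table: pd.DataFrame


def peak(spectrum: np.ndarray) -> float:
    """Maximum over frequency bins excluding DC."""
    return float(np.nanmax(np.asarray(spectrum, dtype=float)[1:]))


def _surrogate_peak_threshold(x, seg_len, metric, n, percentile, rng):
    vals = []
    for _ in range(n):
        surr = phase_randomize(x, rng)
        s = spectral_matrix(surr, seg_len=seg_len)
        vals.append(peak(metric(s)))
    return float(np.quantile(vals, percentile / 100.0, method="lower"))


def sweep_snr(
    model: MVARModel,
    snr_grid_db,
    seed: int | np.random.Generator = 0,
    n_samples: int = 50_000,
    fs: float = 200.0,
    seg_len: int = 256,
    band: tuple[float, float] = (50.0, 60.0),
    pair: tuple[int, int] = (0, 1),
    n_surrogates: int = 0,
    surrogate_percentile: float = 99.9,
) -> SweepResult:
    """Peak coherence / NPD / NPG versus symmetric narrowband SNR.

    Equal observation noise is added to every channel to reach each SNR on
    the grid.  If ``n_surrogates`` > 0, phase-randomization thresholds for
    the peak NPD and NPG statistics are recorded per condition.
    """
    rng = np.random.default_rng(seed)
    i, j = pair
    x0 = simulate(model, n_samples, rng, fs=fs)
    rows = []
    for snr_db in snr_grid_db:
        lam = np.array(
            [lambda_for_snr(x0, ch, snr_db, band, seg_len) for ch in range(x0.n_channels)]
        )
        spec = ObservationSpec(np.eye(x0.n_channels), lam, band)
        y = observe(x0, spec, rng)
        s = spectral_matrix(y, seg_len=seg_len)
        npd = npd_decompose(s, i, j)
        npg = pairwise_npg(s, i, j)
        row = {
            "snr_db": float(snr_db),
            "coherence": peak(npd.coherence),
            "npd_forward": peak(npd.forward),
            "npg_forward": peak(npg.granger[(i, j)]),
        }
        if n_surrogates > 0:
            row["npd_threshold"] = _surrogate_peak_threshold(
                y, seg_len, lambda s_: npd_decompose(s_, i, j).forward,
                n_surrogates, surrogate_percentile, rng,
            )
            row["npg_threshold"] = _surrogate_peak_threshold(
                y, seg_len, lambda s_: pairwise_npg(s_, i, j).granger[(i, j)],
                n_surrogates, surrogate_percentile, rng,
            )
        rows.append(row)
    return SweepResult("snr_db", pd.DataFrame(rows))


def symmetric_two_node_model(
    lag: int = 2, coupling: float = 0.5, osc_freq: float = 55.0, fs: float = 200.0
) -> MVARModel:
    """Reciprocally coupled 2-node model with equal lags and coupling."""
    graph = DirectedGraph(2, ((0, 1, lag), (1, 0, lag)))
    return build_periodic_model(graph, osc_freq=osc_freq, fs=fs, coupling=coupling)


def sweep_delta_snr(
    model: MVARModel,
    delta_grid_db,
    fixed_channel_snr_db: float = 13.0,
    seed: int | np.random.Generator = 0,
    n_samples: int = 50_000,
    fs: float = 200.0,
    seg_len: int = 256,
    band: tuple[float, float] = (50.0, 60.0),
) -> SweepResult:
    """Directionality difference versus SNR asymmetry on a symmetric model.

    Channel Y (index 1) is fixed at ``fixed_channel_snr_db``; channel X
    (index 0) sweeps SNR_X = SNR_Y + delta.  Records peak values in each
    direction and their difference Delta FC_XY = peak(X->Y) - peak(Y->X) for
    NPD and NPG (ground truth ~0 on the symmetric model).
    """
    rng = np.random.default_rng(seed)
    x0 = simulate(model, n_samples, rng, fs=fs)
    lam_y = lambda_for_snr(x0, 1, fixed_channel_snr_db, band, seg_len)
    rows = []
    for delta in delta_grid_db:
        lam_x = lambda_for_snr(x0, 0, fixed_channel_snr_db + delta, band, seg_len)
        spec = ObservationSpec(np.eye(2), np.array([lam_x, lam_y]), band)
        y = observe(x0, spec, rng)
        s = spectral_matrix(y, seg_len=seg_len)
        npd_xy = npd_decompose(s, 0, 1)
        npg = pairwise_npg(s, 0, 1)
        p_npd_xy = peak(npd_xy.forward)
        p_npd_yx = peak(npd_xy.reverse)
        p_npg_xy = peak(npg.granger[(0, 1)])
        p_npg_yx = peak(npg.granger[(1, 0)])
        rows.append(
            {
                "delta_snr_db": float(delta),
                "npd_xy": p_npd_xy,
                "npd_yx": p_npd_yx,
                "delta_npd": p_npd_xy - p_npd_yx,
                "npg_xy": p_npg_xy,
                "npg_yx": p_npg_yx,
                "delta_npg": p_npg_xy - p_npg_yx,
            }
        )
    return SweepResult("delta_snr_db", pd.DataFrame(rows))


def sweep_mixing(
    model: MVARModel,
    shared_variance_grid,
    seed: int | np.random.Generator = 0,
    n_samples: int = 50_000,
    fs: float = 200.0,
    seg_len: int = 256,
    pair: tuple[int, int] = (0, 1),
) -> SweepResult:
    """Peak coherence, lagged NPD, zero-lag NPD and NPG versus signal mixing.

    No observation noise; a symmetric unit-diagonal mixing matrix is
    calibrated to each target shared-variance level.
    """
    rng = np.random.default_rng(seed)
    i, j = pair
    x0 = simulate(model, n_samples, rng, fs=fs)
    n = x0.n_channels
    rows = []
    for v in shared_variance_grid:
        mix = mixing_matrix(n, float(v))
        y = observe(x0, ObservationSpec(mix, np.zeros(n)), rng)
        s = spectral_matrix(y, seg_len=seg_len)
        npd = npd_decompose(s, i, j)
        npg = pairwise_npg(s, i, j)
        rows.append(
            {
                "shared_variance": float(v),
                "coherence": peak(npd.coherence),
                "npd_forward": peak(npd.forward),
                "npd_zero": peak(npd.zero),
                "npg_forward": peak(npg.granger[(i, j)]),
            }
        )
    return SweepResult("shared_variance", pd.DataFrame(rows))


def sweep_conditioning_snr(
    architecture: str,
    ref_snr_grid_db,
    seed: int | np.random.Generator = 0,
    n_samples: int = 50_000,
    fs: float = 200.0,
    seg_len: int = 256,
    band: tuple[float, float] = (50.0, 60.0),
    coupling: float = 0.5,
    osc_freq: float = 55.0,
) -> SweepResult:
    """Effect of incomplete observation of the reference channel Z.

    For the chosen 3-node topology (serial X->Z->Y, feedforward X->Y->Z, or
    recurrent X->Y->Z->X) the SNR of channel Z is swept; per condition the
    unconditioned NPD, NPD(Z), pairwise NPG and multivariate NPG of the
    X -> Y pair are recorded (``inf`` in the grid means noise-free Z).
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"architecture must be one of {sorted(ARCHITECTURES)}")
    rng = np.random.default_rng(seed)
    graph = DirectedGraph(3, ARCHITECTURES[architecture])
    model = build_periodic_model(graph, osc_freq=osc_freq, fs=fs, coupling=coupling)
    x0 = simulate(model, n_samples, rng, fs=fs)
    rows = []
    for snr_db in ref_snr_grid_db:
        lam = np.zeros(3)
        lam[2] = lambda_for_snr(x0, 2, float(snr_db), band, seg_len)
        y = observe(x0, ObservationSpec(np.eye(3), lam, band), rng)
        s = spectral_matrix(y, seg_len=seg_len)
        npd = npd_decompose(s, 0, 1)
        npd_z = conditioned_npd(s, 0, 1, ref=2)
        npg = pairwise_npg(s, 0, 1)
        mvnpg = multivariate_npg(s)
        rows.append(
            {
                "ref_snr_db": float(snr_db),
                "npd_xy": peak(npd.forward),
                "npd_cond_xy": peak(npd_z.forward),
                "npg_xy": peak(npg.granger[(0, 1)]),
                "mvnpg_xy": peak(mvnpg.granger[(0, 1)]),
            }
        )
    return SweepResult("ref_snr_db", pd.DataFrame(rows))


def fit_logistic(x, y) -> LogisticFit:
    """Least-squares logistic fit with multi-start initialization.

    Raises on degenerate (constant) input; returns the fit with its R^2 so
    callers can apply the R^2 > 0.95 reporting rule via ``fit.reliable``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need at least 5 paired points")
    if np.ptp(y) == 0:
        raise ValueError("constant response: logistic midpoint is undefined")

    def logistic(xv, a, x0, k):
        return a / (1.0 + np.exp(-k * (xv - x0)))

    span = np.ptp(x)
    best = None
    for x0_init in np.linspace(x.min(), x.max(), 7):
        for k_init in (0.05, 0.1, 0.3, 1.0):
            try:
                popt, _ = curve_fit(
                    logistic,
                    x,
                    y,
                    p0=[float(y.max()), float(x0_init), k_init],
                    maxfev=20_000,
                )
            except RuntimeError:
                continue
            resid = y - logistic(x, *popt)
            sse = float(np.sum(resid**2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise RuntimeError("logistic fit did not converge from any start")
    sse, (a, x0_fit, k) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    # keep the midpoint inside (a modest extrapolation of) the sampled range
    if not (x.min() - span <= x0_fit <= x.max() + span):
        raise RuntimeError("logistic midpoint fell far outside the sampled range")
    return LogisticFit(maximum=float(a), midpoint=float(x0_fit), steepness=float(k), r_squared=r2)
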