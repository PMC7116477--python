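"""Multivariate autoregressive (MVAR) models and simulation.

The generative process used throughout the package is an order-P MVAR model

    X_t = c + sum_{i=1..P} A_i X_{t-i} + eps_t,    eps_t ~ N(0, R)

with N channels, coefficient matrices ``A_i`` (N x N), constants ``c`` and
innovation covariance ``R``.  Periodic single-node dynamics are engineered by
placing an AR(2) resonator on the diagonal (a complex pole pair at a chosen
frequency), and directed coupling by non-zero off-diagonal coefficients at
lags >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MVARModel",
    "DirectedGraph",
    "TimeSeriesData",
    "build_periodic_model",
    "is_stable",
    "companion_matrix",
    "simulate",
    "random_graph",
    "transfer_function",
    "analytic_spectral_matrix",
]


@dataclass(frozen=True)
class TimeSeriesData:
    """Multichannel time series: ``data`` is (n_channels, n_samples) at rate ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[1] < 1:
            raise ValueError("data must be a 2-D (n_channels, n_samples) array with T >= 1")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        if self.channel_names is not None and len(self.channel_names) != data.shape[0]:
            raise ValueError("channel_names length must match n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    def names(self) -> tuple[str, ...]:
        if self.channel_names is not None:
            return self.channel_names
        return tuple(f"ch{i}" for i in range(self.n_channels))


@dataclass(frozen=True)
class MVARModel:
    """Order-P MVAR model with N channels.

    Parameters
    ----------
    coeffs : ndarray, shape (P, N, N)
        Autoregressive coefficient matrices A_1 .. A_P.  ``coeffs[i-1][a, b]``
        is the influence of channel ``b`` at lag ``i`` on channel ``a``.
    constants : ndarray, shape (N,)
        Constant term c.
    noise_cov : ndarray, shape (N, N)
        Innovation covariance R (symmetric positive definite).
    """

    coeffs: np.ndarray
    constants: np.ndarray
    noise_cov: np.ndarray

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (P, N, N)")
        constants = np.asarray(self.constants, dtype=float).ravel()
        noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = coeffs.shape[1]
        if constants.shape != (n,):
            raise ValueError("constants must have length N")
        if noise_cov.shape != (n, n):
            raise ValueError("noise_cov must be N x N")
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "constants", constants)
        object.__setattr__(self, "noise_cov", noise_cov)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class DirectedGraph:
    """Directed graph on ``n_nodes`` with edges (source, target, lag), lag in [1, 3]."""

    n_nodes: int
    edges: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    min_lag: int = 1
    max_lag: int = 3

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        edges = tuple(tuple(int(v) for v in e) for e in self.edges)
        seen = set()
        for s, t, lag in edges:
            if s == t:
                raise ValueError("self-edges are not allowed")
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ValueError(f"edge ({s}, {t}) out of range")
            if not (self.min_lag <= lag <= self.max_lag):
                raise ValueError(f"edge lag {lag} outside [{self.min_lag}, {self.max_lag}]")
            if (s, t) in seen:
                raise ValueError(f"duplicate edge ({s}, {t})")
            seen.add((s, t))
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix M with M[target, source] ... no: M[s, t]?

        Convention: ``M[i, j]`` is True iff there is a directed edge i -> j.
        """
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for s, t, _ in self.edges:
            m[s, t] = True
        return m


def companion_matrix(model: MVARModel) -> np.ndarray:
    """NP x NP companion-form matrix of the MVAR model."""
    n, p = model.n_channels, model.order
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(model.coeffs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return comp


def is_stable(model: MVARModel) -> bool:
    """True iff the spectral radius of the companion matrix is below one."""
    eig = np.linalg.eigvals(companion_matrix(model))
    return bool(np.max(np.abs(eig)) < 1.0)


def build_periodic_model(
    graph: DirectedGraph,
    osc_freq: float = 55.0,
    fs: float = 200.0,
    coupling: float = 0.5,
    pole_radius: float = 0.74,
    stability_margin: float = 0.95,
    noise_cov: np.ndarray | None = None,
    max_shrink: int = 60,
) -> MVARModel:
    """Build a stable MVAR model with resonant node dynamics and lagged coupling.

    Each node carries identical autonomous AR(2) dynamics with a complex pole
    pair at angle ``2*pi*osc_freq/fs`` and radius ``pole_radius`` (alternating
    signed diagonal coefficients at lags 1 and 2), producing a rhythm at
    ``osc_freq``.  Each graph edge (s, t, lag) contributes an off-diagonal
    coefficient ``coupling`` in ``A_lag[t, s]``.

    For acyclic graphs the companion eigenvalues are exactly the node poles;
    cyclic coupling (reciprocal or recurrent edges) pushes the spectral
    radius outward, so the pole radius is shrunk geometrically until the
    companion spectral radius falls below ``stability_margin`` (< 1 keeps
    the coupled process away from near-unit-root behaviour, where spectra
    become numerically singular).  Raises if ``max_shrink`` steps do not
    suffice.
    """
    n = graph.n_nodes
    order = max(2, max((lag for _, _, lag in graph.edges), default=2))
    omega0 = 2.0 * np.pi * osc_freq / fs
    r = float(pole_radius)
    if noise_cov is None:
        noise_cov = np.eye(n)
    for _ in range(max_shrink):
        coeffs = np.zeros((order, n, n))
        a1 = 2.0 * r * np.cos(omega0)
        a2 = -r * r
        for k in range(n):
            coeffs[0, k, k] = a1
            coeffs[1, k, k] = a2
        for s, t, lag in graph.edges:
            coeffs[lag - 1, t, s] = coupling
        model = MVARModel(coeffs=coeffs, constants=np.zeros(n), noise_cov=noise_cov)
        radius = np.max(np.abs(np.linalg.eigvals(companion_matrix(model))))
        if radius < stability_margin:
            return model
        r *= 0.97
    raise RuntimeError(
        f"no stable model found for graph with {graph.n_edges} edges "
        f"after {max_shrink} pole-radius shrinkage steps"
    )


def simulate(
    model: MVARModel,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    fs: float = 200.0,
    burn_in: int | None = None,
) -> TimeSeriesData:
    """Simulate ``n_samples`` of the stationary MVAR process.

    A burn-in of ``max(500, 10*P*N)`` samples (overridable) is discarded to
    remove the transient from zero initial conditions.  Deterministic given
    ``seed``.  Raises on unstable models.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not is_stable(model):
        raise ValueError("cannot simulate an unstable MVAR model")
    rng = np.random.default_rng(seed)
    n, p = model.n_channels, model.order
    if burn_in is None:
        burn_in = max(500, 10 * p * n)
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    innov = rng.standard_normal((total, n)) @ chol.T + model.constants
    x = np.zeros((total + p, n))
    coeffs = model.coeffs  # (P, N, N)
    for t in range(total):
        acc = innov[t]
        for i in range(p):
            acc = acc + coeffs[i] @ x[t + p - 1 - i]
        x[t + p] = acc
    out = x[p + burn_in:].T.copy()
    return TimeSeriesData(data=out, fs=fs)


def random_graph(
    n_nodes: int,
    n_edges: int,
    seed: int | np.random.Generator = 0,
    min_lag: int = 1,
    max_lag: int = 3,
) -> DirectedGraph:
    """Uniformly sample ``n_edges`` distinct directed edges with i.i.d. uniform lags."""
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds {max_edges} possible directed edges")
    rng = np.random.default_rng(seed)
    pairs = [(s, t) for s in range(n_nodes) for t in range(n_nodes) if s != t]
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    lags = rng.integers(min_lag, max_lag + 1, size=n_edges)
    edges = tuple((pairs[i][0], pairs[i][1], int(lag)) for i, lag in zip(idx, lags))
    return DirectedGraph(n_nodes=n_nodes, edges=edges, min_lag=min_lag, max_lag=max_lag)


def random_stable_graph_model(
    n_nodes: int,
    n_edges: int,
    seed: int | np.random.Generator = 0,
    coupling: float = 0.5,
    osc_freq: float = 55.0,
    fs: float = 200.0,
    max_retries: int = 50,
) -> tuple[DirectedGraph, MVARModel]:
    """Draw random graphs until the induced periodic MVAR model is stable."""
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        graph = random_graph(n_nodes, n_edges, rng)
        try:
            model = build_periodic_model(
                graph, osc_freq=osc_freq, fs=fs, coupling=coupling
            )
        except RuntimeError:
            continue
        return graph, model
    raise RuntimeError("could not draw a stable random graph model")


def transfer_function(model: MVARModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Closed-form MVAR transfer function H(f) = (I - sum_i A_i e^{-2πi f i/fs})^{-1}.

    Returns an array of shape (F, N, N).
    """
    freqs = np.asarray(freqs, dtype=float)
    n, p = model.n_channels, model.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, P)
    a = np.tensordot(z, model.coeffs, axes=(1, 0))  # (F, N, N)
    return np.linalg.inv(np.eye(n)[None, :, :] - a)


def analytic_spectral_matrix(model: MVARModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Closed-form one-sided cross-spectral density S(f) = 2/fs · H R H* of the model.

    The 2/fs factor puts the result on the same one-sided density scale used
    by the segment-averaged estimator (DC and Nyquist carry the factor too;
    the whitened quantities used downstream are scale invariant).
    """
    h = transfer_function(model, freqs, fs)
    s = h @ model.noise_cov[None, :, :] @ np.conj(np.swapaxes(h, 1, 2))
    return 2.0 / fs * s
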