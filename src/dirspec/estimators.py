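"""scikit-learn style estimators for directed functional connectivity.

These classes wrap the functional API (``spectral``, ``npd``, ``conditioned``,
``npg``) behind the familiar fit / fitted-attribute contract so that
connectivity estimation composes with sklearn model selection and pipelines.
``X`` is an array of shape (n_samples, n_channels) — a single continuous
record with samples along the first axis.

Example
-------
>>> est = NonparametricDirectionality(fs=200.0).fit(X)
>>> est.forward_[(0, 1)]   # forward NPD spectrum X0 -> X1
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .conditioned import conditioned_npd
from .mvar import TimeSeriesData
from .npd import npd_decompose
from .npg import multivariate_npg, pairwise_npg, wilson_factorize
from .spectral import coherence as _coherence
from .spectral import spectral_matrix

__all__ = [
    "CoherenceEstimator",
    "NonparametricDirectionality",
    "ConditionedDirectionality",
    "NonparametricGranger",
]


class _SpectralBase(BaseEstimator):
    """Shared input validation and spectral-matrix estimation."""

    def __init__(self, fs: float = 200.0, seg_len: int = 256):
        self.fs = fs
        self.seg_len = seg_len

    def _fit_spectral(self, X):
        X = check_array(X, ensure_min_samples=2 * self.seg_len, ensure_min_features=1)
        ts = TimeSeriesData(data=np.asarray(X, dtype=float).T, fs=self.fs)
        self.n_channels_ = ts.n_channels
        self.spectral_ = spectral_matrix(ts, seg_len=self.seg_len)
        self.freqs_ = self.spectral_.freqs
        return self


class CoherenceEstimator(_SpectralBase):
    """Magnitude-squared coherence for every channel pair.

    Attributes
    ----------
    coherence_ : dict[(i, j), ndarray]
        Coherence spectrum per unordered pair (stored with i < j).
    """

    def fit(self, X, y=None):
        self._fit_spectral(X)
        self.coherence_ = {
            (i, j): _coherence(self.spectral_, i, j)
            for i in range(self.n_channels_)
            for j in range(i + 1, self.n_channels_)
        }
        return self


class NonparametricDirectionality(_SpectralBase):
    """NPD decomposition of coherence for every ordered channel pair.

    Attributes
    ----------
    forward_, reverse_, zero_ : dict[(i, j), ndarray]
        Component spectra per ordered pair; ``forward_[(i, j)]`` is i -> j.
    results_ : dict[(i, j), NPDResult]
        Full per-pair results (scalar components, lag correlations).
    """

    def fit(self, X, y=None):
        self._fit_spectral(X)
        self.results_ = {}
        self.forward_ = {}
        self.reverse_ = {}
        self.zero_ = {}
        for i in range(self.n_channels_):
            for j in range(self.n_channels_):
                if i == j:
                    continue
                res = npd_decompose(self.spectral_, i, j)
                self.results_[(i, j)] = res
                self.forward_[(i, j)] = res.forward
                self.reverse_[(i, j)] = res.reverse
                self.zero_[(i, j)] = res.zero
        return self


class ConditionedDirectionality(_SpectralBase):
    """NPD conditioned on a reference channel (NPD(ref)) for the remaining pairs."""

    def __init__(self, ref: int = 0, fs: float = 200.0, seg_len: int = 256):
        super().__init__(fs=fs, seg_len=seg_len)
        self.ref = ref

    def fit(self, X, y=None):
        self._fit_spectral(X)
        if not (0 <= self.ref < self.n_channels_):
            raise ValueError(f"ref={self.ref} out of range for {self.n_channels_} channels")
        self.results_ = {}
        self.forward_ = {}
        for i in range(self.n_channels_):
            for j in range(self.n_channels_):
                if i == j or self.ref in (i, j):
                    continue
                res = conditioned_npd(self.spectral_, i, j, ref=self.ref)
                self.results_[(i, j)] = res
                self.forward_[(i, j)] = res.forward
        return self


class NonparametricGranger(_SpectralBase):
    """Non-parametric Granger causality from Wilson spectral factorization.

    Parameters
    ----------
    multivariate : bool
        If True (default) factorize the full channel set once (mvNPG);
        otherwise factorize each 2x2 submatrix (pairwise NPG).

    Attributes
    ----------
    granger_ : dict[(i, j), ndarray]
        Causal spectrum per ordered pair.
    noise_cov_ : ndarray
        Innovation covariance of the full factorization (multivariate only).
    """

    def __init__(self, multivariate: bool = True, fs: float = 200.0, seg_len: int = 256):
        super().__init__(fs=fs, seg_len=seg_len)
        self.multivariate = multivariate

    def fit(self, X, y=None):
        self._fit_spectral(X)
        if self.multivariate:
            res = multivariate_npg(self.spectral_)
            self.granger_ = dict(res.granger)
            self.instantaneous_ = dict(res.instantaneous)
            self.noise_cov_ = wilson_factorize(self.spectral_).noise_cov
        else:
            self.granger_ = {}
            self.instantaneous_ = {}
            for i in range(self.n_channels_):
                for j in range(i + 1, self.n_channels_):
                    res = pairwise_npg(self.spectral_, i, j)
                    self.granger_.update(res.granger)
                    self.instantaneous_.update(res.instantaneous)
        return self

    def peak_matrix(self) -> np.ndarray:
        """Matrix of peak causal values (DC excluded); entry [i, j] is i -> j."""
        check_is_fitted(self, "granger_")
        out = np.zeros((self.n_channels_, self.n_channels_))
        for (i, j), spec in self.granger_.items():
            out[i, j] = np.nanmax(spec[1:])
        return out
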