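"""Observation model: instantaneous mixing, z-standardization and additive noise.

Observed channels are built from latent channels X as

    Y = z(L X) + lambda * gamma

where L is a unit-diagonal mixing matrix (volume conduction), z(.) is
per-channel standardization to zero mean and unit variance, gamma is i.i.d.
zero-mean unit-variance white noise and lambda scales the noise per channel,
setting the effective SNR.  SNR is accounted for in decibels over a narrow
frequency band (peak frequency +/- 5 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import TimeSeriesData

__all__ = [
    "ObservationSpec",
    "observe",
    "narrowband_snr_db",
    "lambda_for_snr",
    "mixing_for_shared_variance",
    "band_power",
]

#: Sentinel for a noise-free (infinite SNR) channel.
INF_SNR = np.inf


@dataclass(frozen=True)
class ObservationSpec:
    """Mixing matrix L (unit diagonal), per-channel noise scales and SNR band."""

    mixing: np.ndarray
    noise_scale: np.ndarray
    snr_band: tuple[float, float] = (50.0, 60.0)

    def __post_init__(self):
        mixing = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        noise_scale = np.asarray(self.noise_scale, dtype=float).ravel()
        if mixing.shape[0] != mixing.shape[1]:
            raise ValueError("mixing matrix must be square")
        if not np.allclose(np.diag(mixing), 1.0, atol=1e-12):
            raise ValueError("mixing matrix must have a unit diagonal")
        if noise_scale.shape[0] != mixing.shape[0]:
            raise ValueError("noise_scale must have one entry per channel")
        if np.any(noise_scale < 0):
            raise ValueError("noise_scale entries must be non-negative")
        object.__setattr__(self, "mixing", mixing)
        object.__setattr__(self, "noise_scale", noise_scale)

    @classmethod
    def identity(cls, n_channels: int, snr_band: tuple[float, float] = (50.0, 60.0)):
        return cls(np.eye(n_channels), np.zeros(n_channels), snr_band)


def observe(
    x: TimeSeriesData,
    spec: ObservationSpec,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesData:
    """Apply mixing, z-standardization and additive white observation noise."""
    if spec.mixing.shape[0] != x.n_channels:
        raise ValueError("mixing matrix is not conformable with the time series")
    rng = np.random.default_rng(seed)
    mixed = spec.mixing @ x.data
    mu = mixed.mean(axis=1, keepdims=True)
    sd = mixed.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-standardize a constant channel")
    standardized = (mixed - mu) / sd
    noise = rng.standard_normal(standardized.shape)
    out = standardized + spec.noise_scale[:, None] * noise
    return TimeSeriesData(data=out, fs=x.fs, channel_names=x.channel_names)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Mean power spectral density within a closed frequency band."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} contains no frequency bins")
    return float(np.mean(psd[mask]))


def narrowband_snr_db(
    freqs: np.ndarray,
    signal_psd: np.ndarray,
    noise_psd: np.ndarray,
    band: tuple[float, float],
) -> float:
    """10·log10 of the ratio of mean in-band signal power to mean in-band noise power.

    Returns ``+inf`` as an explicit sentinel when the noise power in the band
    is exactly zero.
    """
    p_sig = band_power(freqs, signal_psd, band)
    p_noise = band_power(freqs, noise_psd, band)
    if p_noise == 0.0:
        return INF_SNR
    return float(10.0 * np.log10(p_sig / p_noise))


def _standardized_band_power(
    x: TimeSeriesData, channel: int, band: tuple[float, float], seg_len: int
) -> float:
    # Narrowband PSD of the z-scored channel, estimated with the package's
    # segment-averaged estimator to keep SNR accounting consistent.
    from .spectral import spectral_matrix

    data = x.data[channel]
    z = (data - data.mean()) / data.std()
    s = spectral_matrix(TimeSeriesData(z[None, :], fs=x.fs), seg_len=seg_len)
    return band_power(s.freqs, s.values[:, 0, 0].real, band)


def lambda_for_snr(
    x: TimeSeriesData,
    channel: int,
    target_snr_db: float,
    band: tuple[float, float],
    seg_len: int = 256,
) -> float:
    """Noise scale lambda achieving a target narrowband SNR for one channel.

    The additive noise is white with unit variance, so its one-sided PSD is
    flat at ``2·lambda²/fs``; lambda follows in closed form from the measured
    narrowband power of the (standardized) signal.  ``target_snr_db=inf``
    returns 0 (no noise).
    """
    if not (0 <= channel < x.n_channels):
        raise ValueError(f"channel {channel} out of range")
    if np.isposinf(target_snr_db):
        return 0.0
    if not np.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite or +inf")
    p_sig = _standardized_band_power(x, channel, band, seg_len)
    if p_sig <= 0:
        raise ValueError(f"channel {channel} has no power in band {band}")
    noise_density = p_sig / 10.0 ** (target_snr_db / 10.0)
    return float(np.sqrt(noise_density * x.fs / 2.0))


def mixing_for_shared_variance(shared_variance: float) -> float:
    """Off-diagonal mixing coefficient for a target shared variance.

    Shared variance v is the squared zero-lag correlation that the symmetric
    two-channel mixing matrix [[1, l], [l, 1]] induces on independent
    unit-variance inputs: corr = 2l/(1+l²), v = corr².  Solving for l gives
    ``l = (1 − sqrt(1−c²))/c`` with ``c = sqrt(v)``.
    """
    if not (0.0 <= shared_variance < 1.0):
        raise ValueError("shared_variance must lie in [0, 1)")
    if shared_variance == 0.0:
        return 0.0
    c = float(np.sqrt(shared_variance))
    return (1.0 - np.sqrt(1.0 - c * c)) / c


def mixing_matrix(n_channels: int, shared_variance: float) -> np.ndarray:
    """Unit-diagonal mixing matrix with one shared-variance level for all pairs."""
    l = mixing_for_shared_variance(shared_variance)
    m = np.full((n_channels, n_channels), l)
    np.fill_diagonal(m, 1.0)
    return m
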