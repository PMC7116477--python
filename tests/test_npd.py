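"""Non-parametric directionality: pre-whitening and lag decomposition."""

import numpy as np
import pytest

from dirspec import (
    ObservationSpec,
    TimeSeriesData,
    coherence,
    lag_correlation,
    npd_decompose,
    observe,
    prewhiten,
    spectral_matrix,
)
from dirspec.observation import mixing_matrix

FS = 200.0


class TestPrewhiten:
    def test_unit_diagonal(self, common_drive_spectral):
        fw = prewhiten(common_drive_spectral)
        diag = np.einsum("fii->fi", fw.values)
        np.testing.assert_allclose(diag, 1.0, atol=1e-10)

    def test_offdiagonal_magnitude_is_coherence(self, common_drive_spectral):
        fw = prewhiten(common_drive_spectral)
        coh = coherence(common_drive_spectral, 0, 1)
        np.testing.assert_allclose(np.abs(fw.values[:, 1, 0]) ** 2, coh, atol=1e-10)

    def test_white_input_already_white(self, white_noise_spectral):
        fw = prewhiten(white_noise_spectral)
        s = white_noise_spectral
        scale = np.sqrt(s.values[:, 0, 0].real * s.values[:, 1, 1].real)
        np.testing.assert_allclose(
            fw.values[:, 0, 1], s.values[:, 0, 1] / scale, atol=1e-12
        )

    def test_zero_autospectrum_reported(self, common_drive_spectral):
        s = common_drive_spectral
        bad = s.values.copy()
        bad[5, 1, 1] = 0.0
        broken = type(s)(
            freqs=s.freqs, values=bad, n_segments=s.n_segments,
            seg_len=s.seg_len, fs=s.fs,
        )
        with pytest.raises(ValueError, match="channel 1"):
            prewhiten(broken)


class TestLagCorrelation:
    def test_pure_delay_peaks_at_delay(self):
        rng = np.random.default_rng(17)
        d = 5
        src = rng.standard_normal(40_000)
        tgt = np.roll(src, d) + 0.05 * rng.standard_normal(40_000)
        x = TimeSeriesData(np.vstack([src, tgt]), fs=FS)
        fw = prewhiten(spectral_matrix(x, 256))
        lags, rho = lag_correlation(fw, 0, 1)
        assert lags[np.argmax(np.abs(rho))] == d

    def test_instantaneous_mixing_peaks_at_zero(self):
        rng = np.random.default_rng(18)
        x = TimeSeriesData(rng.standard_normal((2, 40_000)), fs=FS)
        y = observe(x, ObservationSpec(mixing_matrix(2, 0.4), np.zeros(2)), seed=0)
        fw = prewhiten(spectral_matrix(y, 256))
        lags, rho = lag_correlation(fw, 0, 1)
        assert lags[np.argmax(np.abs(rho))] == 0

    def test_parseval_identity(self, common_drive_spectral):
        fw = prewhiten(common_drive_spectral)
        _, rho = lag_correlation(fw, 0, 1)
        # sum of rho^2 equals the mean coherence over the two-sided grid
        coh = np.abs(fw.values[:, 1, 0]) ** 2
        m = fw.seg_len // 2
        two_sided_mean = (coh[0] + coh[m] + 2 * np.sum(coh[1:m])) / fw.seg_len
        assert np.sum(rho**2) == pytest.approx(two_sided_mean, abs=1e-8)


class TestNpdDecompose:
    def test_additivity_at_every_frequency(self, common_drive_spectral):
        res = npd_decompose(common_drive_spectral, 0, 1)
        np.testing.assert_allclose(
            res.forward + res.reverse + res.zero, res.coherence, atol=1e-8
        )

    def test_components_nonnegative(self, common_drive_spectral):
        res = npd_decompose(common_drive_spectral, 0, 1)
        for comp in (res.forward, res.reverse, res.zero):
            assert np.all(comp >= 0)

    def test_scalar_parseval_split(self, common_drive_spectral):
        res = npd_decompose(common_drive_spectral, 0, 1)
        assert res.scalar_total == pytest.approx(np.sum(res.rho**2), abs=1e-8)

    def test_direction_labels_swap_under_argument_exchange(self, common_drive_spectral):
        ij = npd_decompose(common_drive_spectral, 0, 1)
        ji = npd_decompose(common_drive_spectral, 1, 0)
        np.testing.assert_allclose(ij.forward, ji.reverse, atol=1e-12)
        np.testing.assert_allclose(ij.reverse, ji.forward, atol=1e-12)
        np.testing.assert_allclose(ij.zero, ji.zero, atol=1e-12)
        assert ij.scalar_forward == pytest.approx(ji.scalar_reverse, abs=1e-14)

    def test_unidirectional_coupling_loads_forward(self, unidirectional_spectral):
        res = npd_decompose(unidirectional_spectral, 0, 1)
        band = slice(1, None)
        assert np.max(res.forward[band]) > 5 * np.max(res.reverse[band])
        # forward tracks the coherence at the coupling peak
        k = np.argmax(res.coherence[band]) + 1
        assert res.forward[k] == pytest.approx(res.coherence[k], rel=0.1)

    def test_pure_delay_forward_dominates(self):
        rng = np.random.default_rng(19)
        src = rng.standard_normal(50_000)
        tgt = np.roll(src, 4) + 0.2 * rng.standard_normal(50_000)
        x = TimeSeriesData(np.vstack([src, tgt]), fs=FS)
        res = npd_decompose(spectral_matrix(x, 256), 0, 1)
        assert res.scalar_forward >= 0.95 * res.scalar_total

    def test_zero_lag_mixing_loads_zero_component(self):
        rng = np.random.default_rng(20)
        x = TimeSeriesData(rng.standard_normal((2, 50_000)), fs=FS)
        y = observe(x, ObservationSpec(mixing_matrix(2, 0.5), np.zeros(2)), seed=1)
        res = npd_decompose(spectral_matrix(y, 256), 0, 1)
        assert res.scalar_zero >= 0.95 * res.scalar_total

    def test_independent_channels_components_small(self, white_noise_spectral):
        res = npd_decompose(white_noise_spectral, 0, 1)
        for comp in (res.forward, res.reverse, res.zero):
            assert np.max(comp[1:]) < 0.05

    def test_symmetric_reciprocal_model_balanced(self):
        from dirspec.calibration import symmetric_two_node_model
        from dirspec.mvar import simulate

        model = symmetric_two_node_model()
        x = simulate(model, 50_000, seed=23)
        res = npd_decompose(spectral_matrix(x, 256), 0, 1)
        delta = np.max(res.forward[1:]) - np.max(res.reverse[1:])
        assert abs(delta) < 0.1

    def test_same_channel_rejected(self, common_drive_spectral):
        with pytest.raises(ValueError, match="distinct"):
            npd_decompose(common_drive_spectral, 2, 2)
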