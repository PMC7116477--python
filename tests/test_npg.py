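"""Wilson factorization and non-parametric Granger causality."""

import numpy as np
import pytest

from dirspec import (
    DirectedGraph,
    MVARModel,
    TimeSeriesData,
    analytic_spectral_matrix,
    build_periodic_model,
    multivariate_npg,
    pairwise_npg,
    simulate,
    spectral_matrix,
    wilson_factorize,
)
from dirspec.mvar import transfer_function
from dirspec.spectral import SpectralMatrix

FS = 200.0


def parametric_geweke(model, freqs, fs, i, j):
    """Oracle: Geweke causal spectrum i -> j from the true MVAR coefficients."""
    h = transfer_function(model, freqs, fs)
    r = model.noise_cov
    s = h @ r[None] @ np.conj(np.swapaxes(h, 1, 2))
    sjj = s[:, j, j].real
    sig_partial = r[i, i] - r[j, i] ** 2 / r[j, j]
    return np.log(sjj / (sjj - sig_partial * np.abs(h[:, j, i]) ** 2))


def analytic_as_spectral(model, seg_len=256, fs=FS):
    freqs = np.fft.rfftfreq(seg_len, 1.0 / fs)
    values = analytic_spectral_matrix(model, freqs, fs)
    return SpectralMatrix(freqs=freqs, values=values, n_segments=1000,
                          seg_len=seg_len, fs=fs)


class TestWilsonFactorize:
    def test_recovers_innovation_covariance(self, unidirectional_model):
        # closed-form MVAR spectrum in, innovation covariance out (within 2%)
        s = analytic_as_spectral(unidirectional_model)
        fac = wilson_factorize(s)
        sigma = fac.noise_cov * FS / 2.0  # undo one-sided density scaling
        np.testing.assert_allclose(sigma, unidirectional_model.noise_cov, atol=0.02)

    def test_recovers_transfer_function(self, unidirectional_model):
        s = analytic_as_spectral(unidirectional_model)
        fac = wilson_factorize(s)
        h_true = transfer_function(unidirectional_model, s.freqs, FS)
        assert np.max(np.abs(fac.transfer - h_true)) < 0.01

    def test_reconstruction_residual_tight_on_analytic_input(self, unidirectional_model):
        fac = wilson_factorize(analytic_as_spectral(unidirectional_model))
        assert fac.residual < 1e-6

    def test_reconstruction_on_estimated_input(self, unidirectional_spectral):
        fac = wilson_factorize(unidirectional_spectral)
        s = unidirectional_spectral
        recon = fac.transfer @ fac.noise_cov @ np.conj(np.swapaxes(fac.transfer, 1, 2))
        rel = np.linalg.norm(recon - s.values, axis=(1, 2)) / np.linalg.norm(
            s.values, axis=(1, 2)
        )
        assert np.max(rel) == pytest.approx(fac.residual, rel=1e-6)
        assert fac.residual < 1e-2

    def test_minimum_phase_normalization(self, unidirectional_spectral):
        fac = wilson_factorize(unidirectional_spectral)
        # H has identity zero-lag coefficient: mean over the two-sided grid
        m = unidirectional_spectral.seg_len // 2
        full = np.empty((2 * m, 2, 2), dtype=complex)
        full[: m + 1] = fac.transfer
        full[m + 1:] = np.conj(fac.transfer[1:m][::-1])
        h0 = np.real(np.fft.ifft(full, axis=0)[0])
        np.testing.assert_allclose(h0, np.eye(2), atol=1e-6)
        # Sigma symmetric positive definite
        np.testing.assert_allclose(fac.noise_cov, fac.noise_cov.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(fac.noise_cov)) > 0

    def test_diagonal_input_gives_diagonal_factors(self):
        model = MVARModel(
            np.array([np.diag([0.5, -0.4])]), np.zeros(2), np.diag([1.0, 2.0])
        )
        fac = wilson_factorize(analytic_as_spectral(model))
        off = np.abs(fac.transfer[:, 0, 1]) + np.abs(fac.transfer[:, 1, 0])
        assert np.max(off) < 1e-6
        assert abs(fac.noise_cov[0, 1]) < 1e-9

    def test_rank_deficient_input_reported(self):
        rng = np.random.default_rng(44)
        d = rng.standard_normal(20_000)
        x = TimeSeriesData(np.vstack([d, d]), fs=FS)  # identical channels
        s = spectral_matrix(x, 256)
        with pytest.raises((ValueError, RuntimeError)):
            wilson_factorize(s)


class TestPairwiseNpg:
    def test_matches_parametric_oracle(self, unidirectional_model):
        x = simulate(unidirectional_model, 200_000, seed=13)
        s = spectral_matrix(x, 256)
        npg = pairwise_npg(s, 0, 1)
        fwd_oracle = parametric_geweke(unidirectional_model, s.freqs, FS, 0, 1)
        rev_oracle = parametric_geweke(unidirectional_model, s.freqs, FS, 1, 0)
        assert np.max(np.abs(npg.granger[(0, 1)] - fwd_oracle)) < 0.05
        assert np.max(np.abs(npg.granger[(1, 0)] - rev_oracle)) < 0.05

    def test_independent_channels_near_zero(self, white_noise_spectral):
        npg = pairwise_npg(white_noise_spectral, 0, 1)
        assert np.nanmax(npg.granger[(0, 1)][1:]) < 0.05
        assert np.nanmax(npg.granger[(1, 0)][1:]) < 0.05

    def test_unidirectional_direction_identified(self, unidirectional_spectral):
        npg = pairwise_npg(unidirectional_spectral, 0, 1)
        fwd = np.nanmax(npg.granger[(0, 1)][1:])
        rev = np.nanmax(npg.granger[(1, 0)][1:])
        assert fwd > 0.1
        assert fwd > 5 * rev

    def test_nonnegative_directional_spectra(self, common_drive_spectral):
        npg = pairwise_npg(common_drive_spectral, 0, 1)
        for spec in npg.granger.values():
            valid = spec[~np.isnan(spec)]
            assert np.all(valid >= 0)

    def test_channel_order_invariance(self, unidirectional_data):
        flipped = TimeSeriesData(unidirectional_data.data[::-1].copy(), fs=FS)
        s_fwd = spectral_matrix(unidirectional_data, 256)
        s_rev = spectral_matrix(flipped, 256)
        a = pairwise_npg(s_fwd, 0, 1).granger[(0, 1)]
        b = pairwise_npg(s_rev, 1, 0).granger[(1, 0)]
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestMultivariateNpg:
    def test_two_channels_equals_pairwise(self, unidirectional_spectral):
        pw = pairwise_npg(unidirectional_spectral, 0, 1)
        mv = multivariate_npg(unidirectional_spectral)
        np.testing.assert_allclose(mv.granger[(0, 1)], pw.granger[(0, 1)], atol=1e-8)
        np.testing.assert_allclose(mv.granger[(1, 0)], pw.granger[(1, 0)], atol=1e-8)

    def test_common_drive_spurious_edge_suppressed(self, common_drive_spectral):
        pw = pairwise_npg(common_drive_spectral, 1, 2)
        mv = multivariate_npg(common_drive_spectral)
        assert np.nanmax(pw.granger[(1, 2)][1:]) > 0.1   # pairwise sees it
        assert np.nanmax(mv.granger[(1, 2)][1:]) < 0.05  # full model removes it

    def test_serial_chain_relay_retained(self):
        # X -> Z -> Y: the full-system transfer function carries the relayed
        # route, so the X -> Y estimate is NOT removed (unlike conditioned NPD)
        model = build_periodic_model(DirectedGraph(3, ((0, 2, 2), (2, 1, 2))))
        x = simulate(model, 50_000, seed=41)
        s = spectral_matrix(x, 256)
        mv = multivariate_npg(s)
        assert np.nanmax(mv.granger[(0, 1)][1:]) > 0.2
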