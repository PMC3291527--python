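"""Filter characterization: reverse correlation, Gabor fits, SNR, spectra."""

import numpy as np
import pytest

from robustsc.analysis import (
    effective_filter_size,
    fit_gabor,
    mean_snr,
    population_shapes,
    radial_amplitude_spectrum,
    reverse_correlation,
    whitening_filter,
)
from robustsc.gabor import GaborParams, gabor_patch


class TestReverseCorrelation:
    def test_planted_linear_unit_recovered_from_white_noise(self, rng):
        n, T = 25, 25 * 50
        w = rng.standard_normal(n)
        stimuli = rng.standard_normal((n, T))
        responses = stimuli.T @ w
        est = reverse_correlation(stimuli, responses)[:, 0]
        corr = np.dot(est, w) / (np.linalg.norm(est) * np.linalg.norm(w))
        assert corr >= 0.99

    def test_zero_responses_give_zero_filter(self, rng):
        stimuli = rng.standard_normal((9, 200))
        est = reverse_correlation(stimuli, np.zeros(200))
        assert np.allclose(est, 0.0, atol=1e-10)

    def test_orthonormal_stimuli_noiseless_exact(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((12, 12)))
        w = np.arange(1.0, 13.0)
        responses = Q.T @ w
        est = reverse_correlation(Q, responses)[:, 0]
        assert np.allclose(est, w, atol=1e-8)

    def test_singular_covariance_ridge_fallback(self, rng):
        # rank-deficient stimuli: T < n
        stimuli = rng.standard_normal((20, 5))
        responses = rng.standard_normal(5)
        est = reverse_correlation(stimuli, responses)
        assert np.all(np.isfinite(est))


class TestFitGabor:
    def test_planted_parameter_recovery(self):
        p = GaborParams(x0=7.2, y0=8.4, theta=0.9, f=0.22, phi=1.3,
                        sigma_x=2.4, sigma_y=3.1)
        patch = gabor_patch(p, 16)
        fit = fit_gabor(patch, n_restarts=20, seed=0)
        dtheta = abs((fit.params.theta - p.theta + np.pi / 2) % np.pi
                     - np.pi / 2)
        assert dtheta <= np.deg2rad(5)
        assert abs(fit.params.f - p.f) / p.f <= 0.05
        assert np.hypot(fit.params.x0 - p.x0, fit.params.y0 - p.y0) <= 0.5

    def test_self_consistency_refit_of_fitted_model(self):
        p = GaborParams(x0=6.0, y0=6.0, theta=0.4, f=0.2, phi=0.5,
                        sigma_x=2.0, sigma_y=2.5)
        fit = fit_gabor(gabor_patch(p, 12), n_restarts=10, seed=1)
        model = gabor_patch(fit.params, 12, amplitude=fit.amplitude)
        refit = fit_gabor(model, n_restarts=10, seed=1)
        assert refit.rmse < 1e-10

    def test_pure_noise_patch_does_not_crash(self, rng):
        patch = rng.standard_normal((10, 10))
        fit = fit_gabor(patch, n_restarts=5, seed=2)
        assert np.isfinite(fit.rmse)
        assert fit.rmse <= np.sqrt(np.mean(patch**2)) * 1.5

    def test_seeded_determinism(self, rng):
        patch = rng.standard_normal((8, 8))
        a = fit_gabor(patch, n_restarts=5, seed=7)
        b = fit_gabor(patch, n_restarts=5, seed=7)
        assert a.params == b.params and a.rmse == b.rmse

    def test_shape_parameters_invariant_to_amplitude_rescaling(self):
        p = GaborParams(x0=7.5, y0=7.0, theta=1.2, f=0.25, phi=0.0,
                        sigma_x=2.0, sigma_y=2.0)
        patch = gabor_patch(p, 15)
        a = fit_gabor(patch, n_restarts=8, seed=3)
        b = fit_gabor(5.0 * patch, n_restarts=8, seed=3)
        assert a.nx == pytest.approx(b.nx, abs=1e-3)
        assert a.ny == pytest.approx(b.ny, abs=1e-3)


class TestPopulationShapes:
    def test_discard_rules_and_retained_shape_parameters(self):
        side = 16
        interior = gabor_patch(GaborParams(x0=8, y0=8, theta=0.5, f=0.25,
                                           phi=0.0, sigma_x=2.0, sigma_y=2.0),
                               side)
        edge = gabor_patch(GaborParams(x0=0.2, y0=8.0, theta=0.0, f=0.2,
                                       phi=0.0, sigma_x=2.0, sigma_y=2.0),
                           side)
        tiny = gabor_patch(GaborParams(x0=8, y0=8, theta=0.0, f=0.3,
                                       phi=0.0, sigma_x=0.15, sigma_y=2.0),
                           side)
        filters = np.stack([interior.ravel(), edge.ravel(), tiny.ravel()],
                           axis=1)
        table = population_shapes(filters, side, n_restarts=15, seed=0)
        assert table.loc[0, "discarded"] == ""
        assert table.loc[0, "nx"] == pytest.approx(0.5, abs=0.05)
        assert table.loc[1, "discarded"] == "edge"
        assert table.loc[2, "discarded"] == "too_small"


class TestMeanSNR:
    def test_half_amplitude_closed_form(self, rng):
        X = rng.standard_normal((10, 40))
        assert mean_snr(X, X / 2) == pytest.approx(10 * np.log10(4), abs=1e-9)

    def test_zero_reconstruction_is_zero_db(self, rng):
        X = rng.standard_normal((6, 12))
        assert mean_snr(X, np.zeros_like(X)) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_reconstruction_hits_cap(self, rng):
        X = rng.standard_normal((6, 12))
        assert mean_snr(X, X.copy()) == pytest.approx(100.0)

    def test_zero_norm_column_skipped_with_warning(self, rng):
        X = rng.standard_normal((5, 4))
        X[:, 1] = 0.0
        with pytest.warns(RuntimeWarning):
            out = mean_snr(X, X / 2)
        assert out == pytest.approx(10 * np.log10(4), abs=1e-9)


class TestSpectra:
    def test_impulse_has_flat_spectrum(self):
        patch = np.zeros((16, 16))
        patch[5, 9] = 1.0
        _, curve = radial_amplitude_spectrum(patch[:, :, None], n_bins=8)
        assert np.allclose(curve, 1.0, atol=1e-10)

    def test_sinusoid_peaks_at_its_frequency(self):
        size, f0 = 32, 0.25
        x = np.arange(size)
        img = np.cos(2 * np.pi * f0 * x)[None, :] * np.ones((size, 1))
        freq, curve = radial_amplitude_spectrum(img[:, :, None], n_bins=16)
        assert abs(freq[np.argmax(curve)] - f0) < 0.5 / 16

    def test_white_noise_flat_in_mid_band(self, rng):
        stack = rng.standard_normal((8, 8, 500))
        freq, curve = radial_amplitude_spectrum(stack, n_bins=4)
        # the lowest bin mixes real-valued DC/axis coefficients whose
        # expected amplitude differs; the mid band starts above it
        mid = curve[(freq > 0.1) & (freq < 0.45)]
        assert mid.min() > 0.9 * mid.max()


class TestWhiteningFilter:
    def test_dc_gain_zero_and_ramp_near_origin(self):
        W = whitening_filter(32, f0=0.4)
        assert W[0, 0] == 0.0
        # along the first axis the gain grows on the initial ramp
        profile = W[0, :5]
        assert np.all(np.diff(profile) > 0)

    def test_radial_argmax_at_quarter_power_point(self):
        f0 = 0.3
        f = np.linspace(0, 0.5, 20001)
        gain = f * np.exp(-((f / f0) ** 4))
        assert f[np.argmax(gain)] == pytest.approx(f0 * 0.25**0.25, abs=1e-3)

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            whitening_filter(16, f0=0.9)


class TestEffectiveFilterSize:
    def test_delta_and_flat_filters(self):
        n = 64
        delta = np.zeros((n, 1))
        delta[10, 0] = 1.0
        flat = np.ones((n, 1))
        assert effective_filter_size(delta)[0] == pytest.approx(1 / n)
        assert effective_filter_size(flat)[0] == pytest.approx(
            np.ceil(0.9 * n) / n)

    def test_localized_filter_smaller_than_noise_filter(self, rng):
        noise = rng.standard_normal((64, 1))
        spiky = np.zeros((64, 1))
        spiky[:4, 0] = rng.standard_normal(4)
        assert (effective_filter_size(spiky)[0]
                < effective_filter_size(noise)[0])
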