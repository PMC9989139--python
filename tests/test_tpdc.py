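"""Dual-Kalman MVAR, partial directed coherence and surrogate testing."""

import numpy as np
import pytest

from conftest import FS, bivariate_coupled
from threatnet.preprocess import WindowScheme
from threatnet.synthdata import ar2_coefficients
from threatnet.tpdc import (
    TVMVARModel,
    band_window_summary,
    classify_directionality,
    default_freq_grid,
    direction_classes,
    fit_dekf_mvar,
    fit_ols_mvar,
    pdc_from_coefficients,
    time_reversal_surrogate_test,
    time_reverse,
    tpdc_spectrum,
)

FREQS = default_freq_grid()


def coupled_model(coef=0.5, centre=6.0) -> TVMVARModel:
    """Known generating coefficients of an x -> y coupled oscillator pair."""
    a1, a2 = ar2_coefficients(centre, 0.95, FS)
    A = np.zeros((1, 2, 2, 2))
    A[0, 0] = np.diag([a1, a1])
    A[0, 1] = np.diag([a2, a2])
    A[0, 0, 1, 0] = coef
    return TVMVARModel(A=A, sigma=np.eye(2), order=2, q=0.0, fs=FS, burn_in=0)


class TestPdcSpectrum:
    def test_uncoupled_model_has_zero_offdiagonal(self):
        model = coupled_model(coef=0.0)
        v = tpdc_spectrum(model, FREQS).values
        assert np.allclose(v[0, 1], 0) and np.allclose(v[1, 0], 0)
        assert np.allclose((v**2).sum(axis=1), 1.0, atol=1e-12)

    def test_normalization_identity_random_model(self, rng):
        A = rng.normal(scale=0.2, size=(5, 3, 4, 4))
        v = pdc_from_coefficients(A, FREQS, FS)
        # for every source, squared outflows over targets sum to 1
        assert np.abs((v**2).sum(axis=1) - 1.0).max() < 1e-10

    def test_theta_coupling_peaks_in_band_with_correct_direction(self):
        v = tpdc_spectrum(coupled_model(), FREQS).values[..., 0]
        theta = (FREQS >= 4) & (FREQS <= 8)
        assert v[0, 1, theta].mean() > v[1, 0, theta].mean()
        assert v[0, 1, theta].mean() > v[0, 1, ~theta].mean()

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            tpdc_spectrum(coupled_model(), np.array([200.0]))


class TestBandWindowSummary:
    def make_values(self, fill):
        T = 438
        return np.full((2, 2, len(FREQS), T), fill)

    def test_constant_values_returned_as_is(self):
        scheme = WindowScheme()
        out = band_window_summary(self.make_values(0.37), FREQS, "theta",
                                  scheme, FS, 62)
        assert np.allclose(out["value"], 0.37)
        assert set(out["window"]) == set(scheme.names)

    def test_equals_direct_mean_oracle(self, rng):
        scheme = WindowScheme()
        values = rng.random((2, 2, len(FREQS), 438))
        out = band_window_summary(values, FREQS, "theta", scheme, FS, 62)
        f_idx = np.flatnonzero((FREQS >= 4) & (FREQS <= 8))
        sl = scheme.sample_slice("T2", FS, 62, 438)
        expect = values[0, 1, f_idx, sl.start : sl.stop].mean()
        got = out[(out.source == 0) & (out.target == 1) & (out.window == "T2")]
        assert got["value"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_theta_coupled_model_theta_exceeds_alpha(self):
        scheme = WindowScheme()
        A = np.repeat(coupled_model().A, 438, axis=0)
        model = TVMVARModel(A=A, sigma=np.eye(2), order=2, q=0.0, fs=FS, burn_in=0)
        v = tpdc_spectrum(model, FREQS).values
        theta = band_window_summary(v, FREQS, "theta", scheme, FS, 62)
        alpha = band_window_summary(v, FREQS, "alpha", scheme, FS, 62)
        key = ("source == 0 and target == 1 and window == 'T1'")
        assert theta.query(key)["value"].iloc[0] > alpha.query(key)["value"].iloc[0]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            band_window_summary(self.make_values(0.1), FREQS, (100.0, 110.0),
                                WindowScheme(), FS, 62)


class TestDekf:
    def test_stationary_coupling_matches_ols_oracle(self):
        x = bivariate_coupled(1, 1000, 0.5, seed=3)[0]
        A_ols, _ = fit_ols_mvar(x, 2)
        model = fit_dekf_mvar(x, order=2, q=1e-3, fs=FS)
        est = model.A[300:, 0, 1, 0].mean()
        assert est == pytest.approx(A_ols[0][1, 0], abs=0.1)

    def test_null_coupling_coefficients_near_zero(self):
        x = bivariate_coupled(1, 1000, 0.0, seed=4)[0]
        model = fit_dekf_mvar(x, order=2, q=1e-3, fs=FS)
        cross = model.A[model.burn_in :, 0, [0, 1], [1, 0]]
        assert np.abs(cross.mean(axis=0)).max() < 0.1

    def test_tracks_coefficient_step(self):
        # average over realizations: the tracked coefficient crosses half the
        # step within 200 samples and settles near the new value
        trajs = []
        for seed in range(10):
            x = bivariate_coupled(1, 1000, 0.5, seed=seed, step_at=500)[0]
            model = fit_dekf_mvar(x, order=2, q=1e-3, fs=FS)
            trajs.append(model.A[:, 0, 1, 0])
        mean = np.mean(trajs, axis=0)
        assert abs(mean[300:500].mean()) < 0.15
        assert np.any(mean[500:700] > 0.25)
        assert mean[700:900].mean() == pytest.approx(0.5, abs=0.15)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_dekf_mvar(np.zeros((2, 15)), order=2)


class TestSurrogates:
    def test_time_reverse_is_involution(self, rng):
        x = rng.normal(size=(3, 2, 50))
        assert np.array_equal(time_reverse(time_reverse(x)), x)

    def test_alpha_finer_than_resolution_rejected(self, rng):
        x = rng.normal(size=(4, 2, 300))
        with pytest.raises(ValueError, match="alpha"):
            time_reversal_surrogate_test(x, n_surrogates=50, alpha=0.001)

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError, match="trials"):
            time_reversal_surrogate_test(rng.normal(size=(2, 300)),
                                         n_surrogates=50, alpha=0.05)

    def test_planted_coupling_called_unidirectional(self):
        x = bivariate_coupled(16, 400, 0.5, seed=11)
        res = time_reversal_surrogate_test(
            x, n_surrogates=200, alpha=0.01, order=2, q=1e-3, fs=FS,
            band="theta", seed=0,
        )
        assert res.direction_class[(0, 1)] == "uni(i->j)"

    def test_independent_channels_not_flagged(self):
        x = bivariate_coupled(16, 400, 0.0, seed=12)
        res = time_reversal_surrogate_test(
            x, n_surrogates=200, alpha=0.01, order=2, q=1e-3, fs=FS,
            band="theta", seed=1,
        )
        assert res.direction_class[(0, 1)] == "none"

    def test_directionality_truth_table(self):
        assert classify_directionality(True, True) == "bi"
        assert classify_directionality(True, False) == "uni(i->j)"
        assert classify_directionality(False, True) == "uni(j->i)"
        assert classify_directionality(False, False) == "none"
        mask = np.array([[False, True], [False, False]])
        assert direction_classes(mask) == {(0, 1): "uni(i->j)"}
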