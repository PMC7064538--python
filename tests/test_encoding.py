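import numpy as np
import pandas as pd
import pytest

from iplscan import encoding as E
from iplscan import synth
from iplscan.errors import ConfigError, InvalidParameterError


class TestBuildKernel:
    def test_zero_coefficients_give_zero_kernel(self):
        k = E.build_kernel(np.zeros(E.N_COEF), 1.0)
        np.testing.assert_array_equal(k.taps, np.zeros(64))

    def test_constant_coefficient_gives_near_constant_kernel(self):
        w = np.zeros(E.N_COEF)
        w[0] = 1.0
        k = E.build_kernel(w, 0.9)  # alpha < 1: mask cut beyond the window
        assert np.all(k.taps > 0.9)

    def test_stretch_two_compresses_one_cycle_into_first_half(self):
        # single k=1 sine at alpha=2: a full cycle in [0, 0.5), tail masked
        w = np.zeros(E.N_COEF)
        w[1] = 1.0
        k = E.build_kernel(w, 2.0)
        t = np.arange(64) / 64.0
        first = t < 0.42  # clear of the soft mask roll-off at t = 1/alpha = 0.5
        np.testing.assert_allclose(k.taps[first], np.sin(4 * np.pi * t[first]), atol=0.01)
        assert np.max(np.abs(k.taps[t >= 0.6])) < 0.01

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(InvalidParameterError):
            E.build_kernel(np.zeros(E.N_COEF), 0.0)


class TestPredictResponse:
    def test_zero_kernel_zero_offset_outputs_zero(self, rng):
        k = E.build_kernel(np.zeros(E.N_COEF), 1.0)
        out = E.predict_response(k, 1.0, 0.0, rng.standard_normal(256))
        np.testing.assert_array_equal(out, np.zeros(256))

    def test_elu_contract(self):
        assert E.elu(np.array([1.0]))[0] == 1.0
        assert E.elu(np.array([-50.0]))[0] == pytest.approx(-1.0)
        assert E.elu(np.array([0.0]))[0] == 0.0

    def test_delta_kernel_is_identity_on_nonnegative_input(self, rng):
        # convolution identity oracle: a unit tap at lag 0 passes x through
        taps = np.zeros(64)
        taps[0] = 1.0
        k = E.Kernel(taps=taps, alpha=1.0, coef=np.zeros(E.N_COEF))
        x = np.abs(rng.standard_normal(300))
        np.testing.assert_allclose(E.predict_response(k, 1.0, 0.0, x), x, atol=1e-12)

    def test_rate_mismatch_rejected(self, rng):
        k = E.build_kernel(np.zeros(E.N_COEF), 1.0)
        with pytest.raises(InvalidParameterError):
            E.predict_response(k, 1.0, 0.0, rng.standard_normal(100), rate_hz=30.0)

    def test_prenonlinearity_flips_with_scale_sign(self, rng):
        """The linear stage is equivariant to a sign flip of the scale a."""
        w = synth.default_kernel_coef()
        k = E.build_kernel(w, 1.0)
        x = rng.standard_normal(500)
        L = E.lag_matrix(x)
        conv = L @ k.taps
        np.testing.assert_allclose(-(1.3 * conv), (-1.3) * conv, atol=1e-12)


class TestStretchFromCovariates:
    def test_toy_table_enumeration(self):
        params = {
            "xi": np.array([1.2, 0.8]),
            "psi": np.array([0.1, -0.1]),
            "omega": np.array([[1.0, 2.0], [3.0, 4.0]]),
        }
        cell = [0, 1, 0, 1]
        batch = [0, 0, 1, 1]
        np.testing.assert_allclose(
            E.stretch_from_covariates("depth_stretch", params, cell, batch),
            [1.2, 0.8, 1.2, 0.8],
        )
        np.testing.assert_allclose(
            E.stretch_from_covariates("depth_plus_batch", params, cell, batch),
            [1.3, 0.9, 1.1, 0.7],
        )
        np.testing.assert_allclose(
            E.stretch_from_covariates("depth_batch_interaction", params, cell, batch),
            [1.0, 2.0, 3.0, 4.0],
        )

    def test_psi_zero_reduces_additive_to_depth_only(self, rng):
        xi = rng.uniform(0.5, 1.5, 6)
        params = {"xi": xi, "psi": np.zeros(3)}
        cell = rng.integers(0, 6, 20)
        batch = rng.integers(0, 3, 20)
        np.testing.assert_array_equal(
            E.stretch_from_covariates("depth_plus_batch", params, cell, batch),
            E.stretch_from_covariates("depth_stretch", params, cell, batch),
        )

    def test_interaction_contains_additive(self, rng):
        xi = rng.uniform(0.5, 1.5, 4)
        psi = rng.normal(0, 0.2, 2)
        omega = xi[None, :] + psi[:, None]
        cell = rng.integers(0, 4, 15)
        batch = rng.integers(0, 2, 15)
        np.testing.assert_allclose(
            E.stretch_from_covariates("depth_batch_interaction", {"omega": omega}, cell, batch),
            E.stretch_from_covariates("depth_plus_batch", {"xi": xi, "psi": psi}, cell, batch),
        )

    def test_negative_sum_clipped_with_warning(self):
        params = {"xi": np.array([0.05]), "psi": np.array([-0.5])}
        with pytest.warns(UserWarning):
            out = E.stretch_from_covariates("depth_plus_batch", params, [0], [0])
        assert out[0] == E.ALPHA_FLOOR


class TestZeroCrossing:
    def test_single_sine_cycle(self):
        t = np.arange(64) / 64.0
        k = E.Kernel(taps=np.sin(2 * np.pi * t), alpha=1.0, coef=np.zeros(E.N_COEF))
        # peak at 0.25 s, first sign change after it at 0.5 s
        assert E.kernel_zero_crossing(k) == pytest.approx(0.5, abs=1.5 / 64)

    def test_all_positive_kernel_undefined(self):
        k = E.Kernel(taps=np.ones(64), alpha=1.0, coef=np.zeros(E.N_COEF))
        assert np.isnan(E.kernel_zero_crossing(k))

    def test_stretch_two_halves_crossing_time(self):
        w = synth.default_kernel_coef()
        z1 = E.kernel_zero_crossing(E.build_kernel(w, 1.0))
        z2 = E.kernel_zero_crossing(E.build_kernel(w, 2.0))
        assert z2 == pytest.approx(z1 / 2, abs=1.5 / 64)


@pytest.fixture(scope="module")
def tiny(stim):
    cfg = synth.PopulationConfig(noise_sigma=0.0, psi_sd=0.1)
    rois, truth = synth.sample_population(8, 2, cfg, seed=3)
    tr = synth.simulate_traces(rois, truth, stim, repeats=1, seed=4)
    return synth.population_table(rois), tr.clean, stim


class TestFitSmoke:
    """Small, fast fits; full parameter recovery runs in the acceptance suite."""

    def test_fit_is_deterministic_given_seed(self, tiny):
        tab, Y, stim = tiny
        cfg = E.FitConfig(n_iter=60, polish_iter=0, grid_every=0)
        m1 = E.fit_model("depth_stretch", Y, stim.samples, tab, config=cfg, seed=5)
        m2 = E.fit_model("depth_stretch", Y, stim.samples, tab, config=cfg, seed=5)
        np.testing.assert_array_equal(m1.w, m2.w)
        np.testing.assert_array_equal(m1.alpha, m2.alpha)

    def test_loss_decreases(self, tiny):
        tab, Y, stim = tiny
        cfg = E.FitConfig(n_iter=200, polish_iter=0, grid_every=0)
        m = E.fit_model("per_roi_stretch", Y, stim.samples, tab, config=cfg, seed=0)
        assert m.loss_trace[-1] < m.loss_trace[0]

    def test_covariate_variant_requires_covariates(self, tiny):
        _, Y, stim = tiny
        with pytest.raises(ConfigError):
            E.fit_model("depth_plus_batch", Y, stim.samples, None)

    def test_unknown_variant_rejected(self, tiny):
        tab, Y, stim = tiny
        with pytest.raises(ConfigError):
            E.fit_model("bogus", Y, stim.samples, tab)

    def test_speed_profile_shape_and_psi_table(self, tiny):
        tab, Y, stim = tiny
        cfg = E.FitConfig(n_iter=40, polish_iter=0)
        m = E.fit_model("depth_plus_batch", Y, stim.samples, tab, config=cfg, seed=0)
        profile, psi_tab = E.speed_profile(m)
        assert len(profile) == 10 * 2  # n_bins x 2 polarities
        assert len(psi_tab) == 2
        occupied = profile[profile.n_roi > 0]
        assert len(occupied) >= 1

    def test_speed_profile_undefined_for_per_roi_variants(self, tiny):
        tab, Y, stim = tiny
        cfg = E.FitConfig(n_iter=20, polish_iter=0, grid_every=0)
        m = E.fit_model("per_roi_kernel", Y, stim.samples, tab, config=cfg, seed=0)
        with pytest.raises(ConfigError):
            E.speed_profile(m)
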