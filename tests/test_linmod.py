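import numpy as np
import pandas as pd
import pytest

from iplscan import linmod as L
from iplscan.errors import ConfigError


def make_table(n=40, n_batch=4, seed=0):
    rng = np.random.default_rng(seed)
    depth = rng.uniform(-1, 2, n)
    return pd.DataFrame({
        "polarity": np.where(depth < 0.5, "On", "Off"),
        "depth": depth,
        "batch": [f"b{int(i):02d}" for i in rng.integers(0, n_batch, n)],
    })


class TestBuildDesigns:
    def test_depth_design_has_twenty_columns(self):
        dset = L.build_designs(make_table())
        assert dset.X_depth.shape[1] == 20
        assert (dset.X_depth.sum(axis=1) == 1).all()
        assert (dset.X_polarity.sum(axis=1) == 1).all()

    def test_thirty_seven_batches_give_seventy_two_columns(self):
        tab = make_table(n=400, n_batch=37, seed=3)
        assert tab.batch.nunique() == 37
        dset = L.build_designs(tab)
        assert dset.n_encoded_batches == 36
        assert dset.X_batch.shape[1] == 72
        # reference batch rows are all-zero
        ref = (tab.batch == dset.batch_ids[0]).to_numpy()
        assert dset.X_batch[ref].sum() == 0
        assert (dset.X_batch.sum(axis=1) <= 1).all()

    def test_two_rois_one_per_polarity(self):
        tab = pd.DataFrame({
            "polarity": ["On", "Off"], "depth": [0.0, 1.0], "batch": ["a", "a"],
        })
        dset = L.build_designs(tab)
        np.testing.assert_array_equal(dset.X_polarity, np.eye(2))

    def test_out_of_range_depths_clipped_with_warning(self):
        tab = make_table()
        tab.loc[0, "depth"] = 5.0
        with pytest.warns(UserWarning):
            dset = L.build_designs(tab)
        assert dset.X_depth[0].sum() == 1

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigError):
            L.build_designs(pd.DataFrame({"depth": [0.1], "batch": ["a"]}))


class TestOrthogonalize:
    def test_already_orthogonal_unchanged(self):
        dset = L.build_designs(make_table())
        ortho = np.zeros_like(dset.X_batch)
        dset.X_batch = ortho.copy()
        L.orthogonalize_batch(dset)
        np.testing.assert_allclose(dset.X_batch_orth, ortho)

    def test_batch_equal_to_depth_projects_to_zero(self):
        dset = L.build_designs(make_table())
        dset.X_batch = dset.X_depth.copy()
        L.orthogonalize_batch(dset)
        assert np.max(np.abs(dset.X_batch_orth)) < 1e-10

    def test_random_designs_match_least_squares_residual_oracle(self, rng):
        X_d = rng.standard_normal((60, 8))
        X_b = rng.standard_normal((60, 5))
        dset = L.DesignMatrixSet(
            X_polarity=np.zeros((60, 2)), X_depth=X_d, X_batch=X_b,
        )
        L.orthogonalize_batch(dset)
        # oracle: column-wise least-squares residuals
        for j in range(5):
            coef, *_ = np.linalg.lstsq(X_d, X_b[:, j], rcond=None)
            np.testing.assert_allclose(dset.X_batch_orth[:, j], X_b[:, j] - X_d @ coef, atol=1e-10)
        assert np.max(np.abs(X_d.T @ dset.X_batch_orth)) < 1e-8


class TestFitOls:
    def test_polarity_model_weights_are_group_means(self, rng):
        tab = make_table(n=30)
        dset = L.build_designs(tab)
        Y = rng.standard_normal((30, 100))
        fit = L.fit_ols(dset.X_polarity, Y)
        on = (tab.polarity == "On").to_numpy()
        np.testing.assert_allclose(fit.weights[0], Y[on].mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(fit.weights[1], Y[~on].mean(axis=0), atol=1e-10)

    def test_y_in_design_span_gives_unit_ev(self, rng):
        X = np.kron(np.eye(4), np.ones((5, 1)))
        W = rng.standard_normal((4, 50))
        fit = L.fit_ols(X, X @ W)
        assert np.nanmin(fit.ev) == pytest.approx(1.0)

    def test_four_roi_toy_matches_normal_equations(self, rng):
        X = rng.standard_normal((4, 2))
        Y = rng.standard_normal((4, 6))
        fit = L.fit_ols(X, Y)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(fit.weights, oracle, atol=1e-9)

    def test_underdetermined_design_warns(self, rng):
        with pytest.warns(UserWarning):
            L.fit_ols(rng.standard_normal((3, 5)), rng.standard_normal((3, 10)))


class TestExplainedVariance:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(100)
        assert L.explained_variance(y, y) == pytest.approx(1.0)

    def test_constant_mean_prediction_scores_zero(self, rng):
        y = rng.standard_normal(100)
        assert L.explained_variance(y, np.full(100, y.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self, rng):
        y = rng.standard_normal(100)
        assert L.explained_variance(y, -5 * y) < 0

    def test_zero_variance_trace_rejected(self):
        with pytest.raises(ConfigError):
            L.explained_variance(np.ones(10), np.ones(10))


class TestCompareModels:
    def test_nested_training_monotonicity(self, noisy_dataset):
        tab = noisy_dataset["table"].rename(columns={})
        dset = L.build_designs(
            pd.DataFrame({"polarity": tab.polarity, "depth": tab.depth, "batch": tab.batch})
        )
        cmp_tab = L.compare_models(noisy_dataset["Y"], dset)
        ev = dict(zip(cmp_tab.model, cmp_tab.mean_ev))
        assert ev["polarity"] <= ev["depth"] + 1e-9
        assert ev["depth"] <= ev["batch+depth"] + 1e-9
        assert ev["batch"] <= ev["batch+depth"] + 1e-9

    def test_no_batch_effect_makes_batch_model_match_polarity(self, stim):
        from iplscan import synth

        cfg = synth.PopulationConfig(psi_sd=0.0, noise_sigma=0.3)
        rois, truth = synth.sample_population(80, 4, cfg, seed=21)
        tr = synth.simulate_traces(rois, truth, stim, seed=22)
        tab = synth.population_table(rois)
        dset = L.build_designs(
            pd.DataFrame({"polarity": tab.polarity, "depth": tab.depth, "batch": tab.batch})
        )
        cmp_tab = L.compare_models(tr.repeats.mean(axis=1), dset)
        ev = dict(zip(cmp_tab.model, cmp_tab.mean_ev))
        # with psi = 0, batches differ only through depth composition; the batch
        # model should not beat polarity by much
        assert ev["batch"] <= ev["polarity"] + 0.1
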