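"""Maximum-entropy SDM: features, fitting, prediction, evaluation, selection."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from seedwaste import (
    CovariateStack,
    FeatureSpec,
    build_features,
    bootstrap_ensemble,
    evaluate_auc,
    fit_maxent,
    jackknife_select,
    predict,
    sample_background,
)
from seedwaste.maxent import auc_label, featurize

from oracles import grid_search_maxent, regularized_objective


def _binary_cov(n_bg=1000, n_p=500, q=0.3, p=0.6, seed=0):
    rng = np.random.default_rng(seed)
    bg = (rng.random(n_bg) < q).astype(float)
    pres = (rng.random(n_p) < p).astype(float)
    return {"x": pres}, {"x": bg}


class TestBackground:
    def test_requested_size_is_exact(self, island):
        bg = sample_background(island, 800, seed=1)
        assert bg.n == 800

    def test_all_land_cells_without_replacement(self, island):
        n = island.n_land
        bg = sample_background(island, n, seed=1)
        cells = set(zip(bg.rows.tolist(), bg.cols.tolist()))
        assert len(cells) == n

    def test_seed_controls_sample(self, island):
        a = sample_background(island, 200, seed=1)
        b = sample_background(island, 200, seed=1)
        c = sample_background(island, 200, seed=2)
        assert np.array_equal(a.rows, b.rows)
        assert not np.array_equal(a.rows, c.rows)

    def test_nonpositive_size_rejected(self, island):
        with pytest.raises(ValueError):
            sample_background(island, 0)


class TestFeatures:
    def test_linear_plus_quadratic_count(self):
        cov = {f"v{i}": np.linspace(0, 1, 50) + i for i in range(5)}
        feats = build_features(cov)
        assert len(feats) == 10

    def test_scaling_maps_background_range_to_unit_interval(self):
        bg = {"v": np.array([2.0, 4.0, 6.0])}
        feats = build_features(bg, classes=("linear",))
        f = feats[0]
        assert f({"v": np.array([2.0])})[0] == 0.0
        assert f({"v": np.array([6.0])})[0] == 1.0
        # clamping outside the training range
        assert f({"v": np.array([10.0])})[0] == 1.0
        assert f({"v": np.array([-5.0])})[0] == 0.0

    def test_constant_covariate_dropped_with_warning(self):
        bg = {"c": np.ones(10), "v": np.arange(10.0)}
        with pytest.warns(UserWarning, match="constant"):
            feats = build_features(bg)
        assert all("c" not in f.covariates for f in feats)

    def test_product_features_need_distinct_covariates(self):
        with pytest.raises(ValueError):
            FeatureSpec("product", ("a", "a"), 0.0, 1.0)


class TestFitMaxent:
    def test_single_binary_feature_matches_closed_form(self):
        pres, bg = _binary_cov()
        feats = [FeatureSpec("linear", ("x",), 0.0, 1.0)]
        model = fit_maxent(pres, bg, feats, beta=np.array([0.0]))
        p_hat, q_hat = pres["x"].mean(), bg["x"].mean()
        lam_expected = np.log(p_hat * (1 - q_hat) / (q_hat * (1 - p_hat)))
        assert model.weights[0] == pytest.approx(lam_expected, abs=1e-4)

    def test_no_signal_presences_recover_near_null_model(self, island):
        # presences drawn uniformly from the background carry no signal:
        # default regularization shrinks all weights to ~0, and even the
        # unregularized fit improves on the uniform model by a vanishing
        # gain (raw weights are weakly identified under collinearity, so
        # the model-level statements are the meaningful ones)
        rng = np.random.default_rng(0)
        bg = sample_background(island, 3000, seed=0, predictors=["temp_mean", "precip_total"])
        idx = rng.integers(0, bg.n, size=5000)
        pres = {k: v[idx] for k, v in bg.covariates.items()}
        feats = build_features(bg.covariates)
        model = fit_maxent(pres, bg.covariates, feats)
        assert np.all(np.abs(model.weights) < 0.05)
        m0 = fit_maxent(pres, bg.covariates, feats, beta=np.zeros(len(feats)))
        Fp_mean = featurize(feats, pres).mean(axis=0)
        gain = Fp_mean @ m0.weights - m0.log_normalizer + np.log(bg.n)
        assert gain < 0.005

    def test_huge_regularization_shrinks_weights_to_exact_zero(self):
        pres, bg = _binary_cov()
        feats = [FeatureSpec("linear", ("x",), 0.0, 1.0)]
        model = fit_maxent(pres, bg, feats, beta=np.array([100.0]))
        assert model.weights[0] == 0.0

    def test_raw_distribution_normalises_over_background(self):
        pres, bg = _binary_cov(seed=5)
        feats = [FeatureSpec("linear", ("x",), 0.0, 1.0), FeatureSpec("quadratic", ("x",), 0.0, 1.0)]
        model = fit_maxent(pres, bg, feats)
        assert model.raw(bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_fit_beats_null_model_objective(self):
        pres, bg = _binary_cov(seed=6)
        feats = [FeatureSpec("linear", ("x",), 0.0, 1.0)]
        model = fit_maxent(pres, bg, feats)
        Fp = featurize(feats, pres)
        Fb = featurize(feats, bg)
        assert regularized_objective(model.weights, Fp, Fb, model.beta) <= (
            regularized_objective(np.zeros(1), Fp, Fb, model.beta) + 1e-12
        )

    @pytest.mark.parametrize("beta_scale", [0.0, 0.02, 0.2])
    def test_matches_grid_search_oracle_on_tiny_background(self, beta_scale):
        # <= 10 background cells, 2 features: exhaustive search of the
        # same objective must land on the same weights
        rng = np.random.default_rng(17)
        bg = {"u": rng.uniform(0, 1, 8), "v": rng.uniform(0, 1, 8)}
        pres = {"u": rng.uniform(0.3, 1, 12), "v": rng.uniform(0, 0.7, 12)}
        feats = build_features(bg, classes=("linear",))
        beta = np.full(len(feats), beta_scale)
        model = fit_maxent(pres, bg, feats, beta=beta)
        Fp = featurize(feats, pres)
        Fb = featurize(feats, bg)
        lam_oracle = grid_search_maxent(Fp, Fb, beta)
        assert np.allclose(model.weights, lam_oracle, atol=1e-3)

    def test_too_few_presences_rejected(self):
        feats = [FeatureSpec("linear", ("x",), 0.0, 1.0)]
        with pytest.raises(ValueError):
            fit_maxent({"x": np.array([1.0])}, {"x": np.arange(5.0)}, feats)


class TestPredict:
    def _three_cell_stack(self):
        values = np.array([[0.0, 1.0, 2.0]])
        return CovariateStack(
            cell_size=1.0, origin=(0.0, 0.0),
            layers={"v": values}, mask=np.zeros((1, 3), dtype=bool),
        )

    def test_three_cell_worked_example(self):
        # manual arithmetic: f = (0, 0.5, 1), lambda = 1
        stack = self._three_cell_stack()
        f = np.array([0.0, 0.5, 1.0])
        log_z = logsumexp(f)
        q = np.exp(f - log_z)
        H = -(q * np.log(q)).sum()
        from seedwaste.maxent import MaxentModel
        model = MaxentModel(
            features=[FeatureSpec("linear", ("v",), 0.0, 2.0)],
            weights=np.array([1.0]), beta=np.array([0.0]),
            log_normalizer=float(log_z), entropy=float(H),
        )
        raw = predict(model, stack, "raw")
        np.testing.assert_allclose(raw.values[0], q, rtol=1e-12)
        logistic = predict(model, stack, "logistic")
        expected = np.exp(H) * q / (1 + np.exp(H) * q)
        np.testing.assert_allclose(logistic.values[0], expected, rtol=1e-12)

    def test_uniform_model_predicts_logistic_one_half(self):
        stack = self._three_cell_stack()
        from seedwaste.maxent import MaxentModel
        n = 3
        model = MaxentModel(
            features=[FeatureSpec("linear", ("v",), 0.0, 2.0)],
            weights=np.array([0.0]), beta=np.array([0.0]),
            log_normalizer=float(np.log(n)), entropy=float(np.log(n)),
        )
        surf = predict(model, stack, "logistic")
        np.testing.assert_allclose(surf.values[0], 0.5, rtol=1e-12)

    def test_logistic_preserves_raw_ranking(self, island, wet_species_surface):
        from seedwaste import sample_occurrences, clean_occurrences
        occ = clean_occurrences(sample_occurrences(wet_species_surface, 300, seed=2), island)
        preds = ["precip_dry", "precip_wet"]
        bg = sample_background(island, 1000, seed=3, predictors=preds)
        rows, cols = island.cell_index(occ.x, occ.y)
        feats = build_features(bg.covariates)
        model = fit_maxent(island.covariates_at(preds, rows, cols), bg.covariates, feats)
        raw = predict(model, island, "raw").values[island.land]
        logistic = predict(model, island, "logistic").values[island.land]
        assert spearmanr(raw, logistic).statistic == pytest.approx(1.0)

    def test_missing_covariate_is_named_in_error(self):
        stack = self._three_cell_stack()
        from seedwaste.maxent import MaxentModel
        model = MaxentModel(
            features=[FeatureSpec("linear", ("absent",), 0.0, 1.0)],
            weights=np.array([0.0]), beta=np.array([0.0]),
            log_normalizer=0.0, entropy=0.0,
        )
        with pytest.raises(ValueError, match="absent"):
            predict(model, stack)


class TestAuc:
    def test_perfect_separation_scores_one(self):
        assert evaluate_auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_iid_scores_near_one_half(self):
        rng = np.random.default_rng(3)
        auc = evaluate_auc(rng.random(2000), rng.random(2000))
        assert abs(auc - 0.5) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        p, b = rng.normal(1, 1, 300), rng.normal(0, 1, 500)
        base = evaluate_auc(p, b)
        assert evaluate_auc(np.exp(p), np.exp(b)) == pytest.approx(base)
        assert evaluate_auc(3 * p - 7, 3 * b - 7) == pytest.approx(base)

    def test_discrimination_grade_thresholds(self):
        assert auc_label(0.95) == "very good"
        assert auc_label(0.85) == "good"
        assert auc_label(0.75) == "useable"
        assert auc_label(0.6) == "poor"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([], [0.1])


class TestJackknife:
    def test_generating_covariate_beats_pure_noise(self, island, wet_species_surface):
        from seedwaste import sample_occurrences
        occ = sample_occurrences(wet_species_surface, 500, seed=6)
        preds = ["precip_dry", "noise_a"]
        bg = sample_background(island, 1500, seed=7, predictors=preds)
        rows, cols = island.cell_index(occ.x, occ.y)
        report = jackknife_select(
            island.covariates_at(preds, rows, cols), bg.covariates, preds, k=1
        )
        assert report.selected == ["precip_dry"]
        assert report.gains["precip_dry"] > report.gains["noise_a"]

    def test_selects_k_names_and_gains_nonnegative(self, island, wet_species_surface):
        from seedwaste import sample_occurrences
        occ = sample_occurrences(wet_species_surface, 300, seed=6)
        preds = [k for k in island.layers if k != "elevation"]
        bg = sample_background(island, 1000, seed=8, predictors=preds)
        rows, cols = island.cell_index(occ.x, occ.y)
        report = jackknife_select(
            island.covariates_at(preds, rows, cols), bg.covariates, preds, k=5
        )
        assert len(report.selected) == 5
        assert all(g >= 0 for g in report.gains.values())

    def test_identical_predictors_tie_broken_by_input_order(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(0, 1, 200)
        pres_v = rng.uniform(0.5, 1, 100)
        pres = {"a": pres_v, "b": pres_v.copy()}
        bg = {"a": v, "b": v.copy()}
        report = jackknife_select(pres, bg, ["a", "b"], k=1)
        assert report.selected == ["a"]


class TestBootstrapEnsemble:
    def _setup(self, island, surface, n=300):
        from seedwaste import sample_occurrences
        occ = sample_occurrences(surface, n, seed=10)
        preds = ["precip_dry", "precip_wet"]
        bg = sample_background(island, 1200, seed=11, predictors=preds)
        rows, cols = island.cell_index(occ.x, occ.y)
        feats = build_features(bg.covariates)
        return island.covariates_at(preds, rows, cols), bg, feats

    def test_single_replicate_mean_equals_that_replicate(self, island, wet_species_surface):
        pres, bg, feats = self._setup(island, wet_species_surface)
        surf, report, models = bootstrap_ensemble(pres, bg, feats, island, n_replicates=1, seed=12)
        single = predict(models[0], island, "logistic")
        np.testing.assert_allclose(surf.values, single.values, rtol=1e-12)
        assert report.n_replicates == 1

    def test_report_lists_one_auc_per_replicate(self, island, wet_species_surface):
        pres, bg, feats = self._setup(island, wet_species_surface)
        _, report, _ = bootstrap_ensemble(pres, bg, feats, island, n_replicates=10, seed=13)
        assert len(report.auc_values) == 10

    def test_invalid_arguments_rejected(self, island, wet_species_surface):
        pres, bg, feats = self._setup(island, wet_species_surface)
        with pytest.raises(ValueError):
            bootstrap_ensemble(pres, bg, feats, island, n_replicates=0)
        with pytest.raises(ValueError):
            bootstrap_ensemble(pres, bg, feats, island, n_replicates=2, test_fraction=1.5)
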