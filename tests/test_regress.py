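"""Univariate screen, cohort splitting, PCA, model training, importances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skintopo.regress import (
    ALGORITHMS,
    COVARIATES,
    SCREEN_VARIABLES,
    evaluate,
    overlay_generators,
    pca_reduce,
    predict_subject,
    region_importance,
    split_cohort,
    train_model,
    univariate_screen,
)


class TestUnivariateScreen:
    def test_fourteen_variables(self):
        assert len(SCREEN_VARIABLES) == 14
        assert SCREEN_VARIABLES[:4] == COVARIATES

    def test_matches_linregress_and_bh(self, rng):
        n = 60
        table = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "tewl": rng.normal(size=n),
            }
        )
        table["tewl"] += 2.0 * table["a"]
        out = univariate_screen(table, variables=["a", "b"])
        res = stats.linregress(table["a"], table["tewl"])
        assert out.loc["a", "slope"] == pytest.approx(res.slope)
        assert out.loc["a", "t_value"] == pytest.approx(res.slope / res.stderr)
        assert out.loc["a", "p_value"] == pytest.approx(res.pvalue)
        # BH with two tests: smaller p doubled (capped by the larger step)
        ps = np.sort(out["p_value"].to_numpy())
        expected = min(2 * ps[0], ps[1])
        assert out["fdr"].min() == pytest.approx(min(expected, 1.0))

    def test_strong_signal_detected(self, rng):
        n = 90
        x = rng.normal(size=n)
        table = pd.DataFrame({"a": x, "b": rng.normal(size=n), "tewl": 3 * x + rng.normal(size=n)})
        out = univariate_screen(table, variables=["a", "b"])
        assert out.loc["a", "fdr"] < 0.01
        assert out.loc["a", "t_value"] > 0

    def test_constant_variable_reported_nan(self, rng):
        table = pd.DataFrame(
            {"a": np.ones(20), "b": rng.normal(size=20), "tewl": rng.normal(size=20)}
        )
        out = univariate_screen(table, variables=["a", "b"])
        assert np.isnan(out.loc["a", "p_value"]) and np.isnan(out.loc["a", "fdr"])
        assert np.isfinite(out.loc["b", "fdr"])

    def test_nan_rows_dropped_per_variable(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=30), "tewl": rng.normal(size=30)})
        table.loc[:4, "a"] = np.nan
        out = univariate_screen(table, variables=["a"])
        assert out.loc["a", "n"] == 25


class TestSplitCohort:
    def test_subjects_disjoint_and_complete(self):
        table = pd.DataFrame({"subject_id": np.repeat([f"S{i}" for i in range(10)], 3)})
        train, test = split_cohort(table, 0.7, seed=3)
        assert len(train) == 7 and len(test) == 3
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(table["subject_id"])

    def test_deterministic_under_seed(self):
        table = pd.DataFrame({"subject_id": [f"S{i}" for i in range(20)]})
        a = split_cohort(table, 0.7, seed=5)
        b = split_cohort(table, 0.7, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        c = split_cohort(table, 0.7, seed=6)
        assert not np.array_equal(a[0], c[0])

    def test_never_empty_side(self):
        table = pd.DataFrame({"subject_id": ["A", "B"]})
        train, test = split_cohort(table, 0.99, seed=0)
        assert len(train) == 1 and len(test) == 1

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(pd.DataFrame({"subject_id": ["A", "A"]}))


class TestPca:
    def test_keeps_high_variance_components(self, rng):
        # 2 strong directions + small isotropic noise in 10 columns
        n = 200
        basis = rng.normal(size=(2, 10))
        Z = rng.normal(size=(n, 2)) @ (basis * [[10], [5]]) + 0.05 * rng.normal(size=(n, 10))
        train, test, red = pca_reduce(Z[:150], Z[150:])
        assert red.n_kept == 2
        assert train.shape == (150, 2) and test.shape == (50, 2)

    def test_transform_consistent_with_fit(self, rng):
        X = rng.normal(size=(50, 6))
        train, _, red = pca_reduce(X)
        np.testing.assert_allclose(red.transform(X), train, atol=1e-10)

    def test_constant_columns_tolerated(self, rng):
        X = np.column_stack([rng.normal(size=40), np.full(40, 7.0)])
        train, _, red = pca_reduce(X)
        assert np.all(np.isfinite(train))
        assert red.n_kept >= 1

    def test_min_ratio_one_keeps_single_component(self, rng):
        X = rng.normal(size=(30, 5))
        _, _, red = pca_reduce(X, min_ratio=1.0)
        assert red.n_kept == 1


class TestTrainModel:
    @staticmethod
    def _linear_problem(rng, n_subjects=12, reps=3):
        subjects = np.repeat(np.arange(n_subjects), reps)
        X = rng.normal(size=(len(subjects), 3))
        y = 2.0 * X[:, 0] - X[:, 1] + 0.1 * rng.normal(size=len(subjects))
        return X, y, subjects

    def test_linear_recovers_coefficients(self, rng):
        X, y, subjects = self._linear_problem(rng)
        model = train_model(X, y, subjects, "linear", seed=0)
        np.testing.assert_allclose(model.estimator.coef_, [2.0, -1.0, 0.0], atol=0.1)

    def test_grid_selection_on_cv_rmse(self, rng):
        X, y, subjects = self._linear_problem(rng, n_subjects=10)
        grid = [{"alpha": 1000.0, "l1_ratio": 0.5}, {"alpha": 1e-4, "l1_ratio": 0.5}]
        model = train_model(
            X, y, subjects, "elastic_net", seed=0, cv_repeats=2, cv_folds=5, param_grid=grid
        )
        assert model.params["alpha"] == 1e-4  # the barely-regularized fit wins
        assert len(model.cv_rmse) == 2
        assert model.cv_rmse["rmse"].notna().all()

    def test_deterministic_for_fixed_seed(self, rng):
        X, y, subjects = self._linear_problem(rng, n_subjects=8)
        kw = dict(seed=4, cv_repeats=2, cv_folds=4)
        m1 = train_model(X, y, subjects, "random_forest", **kw)
        m2 = train_model(X, y, subjects, "random_forest", **kw)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        pd.testing.assert_frame_equal(m1.cv_rmse, m2.cv_rmse)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_every_algorithm_fits_and_predicts(self, algorithm, rng):
        X, y, subjects = self._linear_problem(rng, n_subjects=8, reps=2)
        model = train_model(
            X, y, subjects, algorithm, seed=0, cv_repeats=1, cv_folds=3,
            param_grid=[{}] if algorithm != "neural_net" else [{"hidden_layer_sizes": (8,)}],
        )
        pred = model.predict(X)
        assert pred.shape == y.shape and np.all(np.isfinite(pred))

    def test_unknown_algorithm_rejected(self, rng):
        X, y, subjects = self._linear_problem(rng)
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_model(X, y, subjects, "deep_kernel")

    def test_importances_only_for_tree_models(self, rng):
        X, y, subjects = self._linear_problem(rng, n_subjects=6, reps=2)
        rf = train_model(X, y, subjects, "random_forest", param_grid=[{}], cv_repeats=1)
        imp = rf.feature_importances
        assert imp.shape == (3,) and imp.sum() == pytest.approx(1.0)
        lin = train_model(X, y, subjects, "linear")
        with pytest.raises(ValueError, match="no impurity-based importances"):
            _ = lin.feature_importances


class TestAggregationAndMetrics:
    def test_subject_median_aggregation(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["A", "A", "A", "B", "B", "B"],
                "session": 1,
                "tewl": [10.0] * 3 + [20.0] * 3,
            }
        )
        agg = predict_subject(np.array([1.0, 2.0, 9.0, 4.0, 5.0, 6.0]), meta)
        assert len(agg) == 2
        a = agg[agg["subject_id"] == "A"].iloc[0]
        assert a["prediction"] == 2.0 and a["tewl"] == 10.0

    def test_perfect_prediction_metrics(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, rmse, mae = evaluate(y, y)
        assert (r2, rmse, mae) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _, _ = evaluate(np.full(3, 2.0), y)
        assert r2 == pytest.approx(0.0)

    def test_hand_example(self):
        r2, rmse, mae = evaluate(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert rmse == pytest.approx(1.0) and mae == pytest.approx(1.0)

    def test_zero_variance_observations_nan_r2(self):
        r2, _, _ = evaluate(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(r2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1.0]), np.array([1.0]))


class TestRegionImportance:
    def test_planted_signal_column_dominates(self, rng):
        n_subjects, reps, total = 20, 2, 12
        subjects = np.repeat([f"S{i:02d}" for i in range(n_subjects)], reps)
        features = rng.normal(size=(len(subjects), total))
        covariates = rng.normal(size=(len(subjects), 4))
        response = 5.0 * features[:, 7] + 0.2 * rng.normal(size=len(subjects))
        res = region_importance(
            features,
            covariates,
            response,
            subjects,
            n_regions_total=total,
            grid=(3, 4),
            use_pca=False,
            n_repeats=3,
            seed=1,
        )
        assert res.region.argmax() == 7
        assert res.region.sum() == pytest.approx(1.0)
        assert res.per_repeat.shape == (3, total)
        assert set(res.covariates) == set(COVARIATES)

    def test_block_index_scatter(self, rng):
        # reduced columns 2 and 5 of a length-8 region vector
        subjects = np.repeat([f"S{i}" for i in range(12)], 2)
        features = rng.normal(size=(len(subjects), 2))
        response = 3.0 * features[:, 1] + 0.1 * rng.normal(size=len(subjects))
        res = region_importance(
            features,
            rng.normal(size=(len(subjects), 4)),
            response,
            subjects,
            feature_block_index=np.array([2, 5]),
            n_regions_total=8,
            grid=(2, 2),
            use_pca=False,
            n_repeats=2,
            seed=0,
        )
        assert res.region[[0, 1, 3, 4, 6, 7]].sum() == 0.0
        assert res.region.argmax() == 5


class TestOverlay:
    def test_marks_generators_in_selected_region(self):
        from skintopo.filtration import FiltrationField
        from skintopo.persistence import compute_persistence
        from skintopo.vectorize import fit_range

        vals = np.full((9, 9), 200.0)
        vals[4, 4] = 0.0  # one hole dying at the centre
        vals[0, 0] = 150.0
        d = compute_persistence(FiltrationField(vals, grid_spacing=2))
        cfg = fit_range([d])
        pts_region = None
        # find the region holding the dim-1 point, then overlay it
        from skintopo.diagram import to_midlife_lifetime
        from skintopo.vectorize import _region_index

        pts = to_midlife_lifetime(d)
        sel = pts[pts["dim"] == 1]
        me, le = cfg.edges(1)
        pts_region = (
            int(_region_index(sel["mid_life"].to_numpy(), me)[0]),
            int(_region_index(sel["life_time"].to_numpy(), le)[0]),
        )
        img = np.zeros((18, 18), dtype=np.uint8)
        out = overlay_generators(img, d, pts_region, cfg)
        assert out.shape == (18, 18, 3)
        # death position (4, 4) scales to pixel (8, 8) and is painted blue
        assert tuple(out[8, 8]) == (0, 0, 255)

    def test_empty_region_warns(self):
        from skintopo.filtration import FiltrationField
        from skintopo.persistence import compute_persistence
        from skintopo.vectorize import VectorizerConfig

        vals = np.array([[3.0, 1.0], [1.0, 5.0]])
        d = compute_persistence(FiltrationField(vals))
        cfg = VectorizerConfig(
            ranges={0: (100.0, 101.0, 100.0, 101.0), 1: (0.0, 1.0, 0.0, 1.0)}
        )
        with pytest.warns(UserWarning, match="no generators"):
            out = overlay_generators(np.zeros((2, 2), dtype=np.uint8), d, (5, 5), cfg)
        assert np.all(out == 0)
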