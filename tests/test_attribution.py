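"""Tree Shapley values against brute-force enumeration; importance metrics."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from aqcausal.attribution import (
    dependence_summary,
    fit_impact_model,
    global_importance,
    quality_filter,
    shap_values,
    total_gain_importance,
)
from aqcausal.synthetic import SimConfig, generate_area_impacts


def brute_force_shapley(gbr, X, n_features):
    """Oracle: enumerate all subsets of ALL model features; the value
    function is the cover-weighted conditional expectation by tree
    traversal, composed over the whole ensemble. Independent of the
    production per-tree enumeration."""

    def ensemble_value(x, subset):
        total = float(gbr.init_.constant_.ravel()[0])
        for est in gbr.estimators_.ravel():
            t = est.tree_

            def walk(node):
                if t.children_left[node] == -1:
                    return t.value.reshape(-1)[node]
                f = t.feature[node]
                if f in subset:
                    nxt = (
                        t.children_left[node]
                        if x[f] <= t.threshold[node]
                        else t.children_right[node]
                    )
                    return walk(nxt)
                wl = (
                    t.weighted_n_node_samples[t.children_left[node]]
                    / t.weighted_n_node_samples[node]
                )
                return wl * walk(t.children_left[node]) + (1 - wl) * walk(
                    t.children_right[node]
                )

            total += gbr.learning_rate * walk(0)
        return total

    m = n_features
    phi = np.zeros((len(X), m))
    feats = list(range(m))
    for r, x in enumerate(X):
        for i in feats:
            others = [f for f in feats if f != i]
            for k in range(m):
                w = factorial(k) * factorial(m - k - 1) / factorial(m)
                for S in combinations(others, k):
                    phi[r, i] += w * (
                        ensemble_value(x, set(S) | {i}) - ensemble_value(x, set(S))
                    )
    return phi


@pytest.fixture(scope="module")
def area_world():
    cfg = SimConfig(n_areas=150, seed=13)
    feats, impact, truth = generate_area_impacts(cfg)
    table = feats.drop(columns=["area_id", "x_km", "y_km"])
    return table, impact, truth


@pytest.fixture(scope="module")
def fitted_small():
    """Tiny model (4 features, depth <= 3) for exact-oracle comparison."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
    y = (
        2.0 * (X["a"] > 0)
        - 1.0 * X["b"]
        + 0.5 * X["a"] * X["c"]
        + rng.normal(0, 0.1, 80)
    )
    im = fit_impact_model(
        X, y.to_numpy(), seed=0, tune=False, min_areas=50,
    )
    im.model.set_params()  # no-op; keeps the fixture explicit
    return im, X


class TestFitImpactModel:
    def test_single_feature_step_function_learned(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(120, 5)), columns=list("abcde"))
        y = np.where(X["c"] > 0.2, 4.0, -4.0)
        im = fit_impact_model(X, y, seed=0, tune=False)
        assert im.cv_report["cv_r2"] >= 0.9

    def test_pure_noise_has_no_cv_skill(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(120, 5)), columns=list("abcde"))
        y = rng.normal(size=120)
        im = fit_impact_model(X, y, seed=0, tune=False)
        assert im.cv_report["cv_r2"] <= 0.1

    def test_non_finite_target_lists_areas(self, area_world):
        table, impact, _ = area_world
        bad = impact.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_impact_model(table, bad, seed=0, tune=False)

    def test_determinism(self, area_world):
        table, impact, _ = area_world
        a = fit_impact_model(table, impact, seed=5, tune=False)
        b = fit_impact_model(table, impact, seed=5, tune=False)
        np.testing.assert_array_equal(
            a.model.predict(a.X_train), b.model.predict(b.X_train)
        )

    def test_quality_filter_drops_constant_and_gappy(self):
        df = pd.DataFrame(
            {
                "ok": [1.0, 2.0, 3.0, 4.0, 5.0],
                "const": [1.0] * 5,
                "gappy": [1.0, np.nan, np.nan, np.nan, 2.0],
            }
        )
        assert list(quality_filter(df).columns) == ["ok"]


class TestShapValues:
    def test_matches_brute_force_enumeration(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X.iloc[:12])
        oracle = brute_force_shapley(im.model, X.iloc[:12].to_numpy(), 4)
        np.testing.assert_allclose(expl.values.to_numpy(), oracle, atol=1e-8)

    def test_local_accuracy(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        recon = expl.base_value + expl.values.sum(axis=1).to_numpy()
        np.testing.assert_allclose(recon, expl.predictions, atol=1e-6)

    def test_base_value_is_mean_training_prediction(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        assert expl.base_value == pytest.approx(
            im.model.predict(im.X_train).mean(), abs=1e-6
        )

    def test_unused_feature_gets_exact_zero(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["used", "u2", "dead"])
        y = 3.0 * X["used"] + X["u2"]
        # make "dead" literally constant so no tree can split on it
        X["dead"] = 1.0
        X_fit = X.copy()
        X_fit["dead"] += rng.normal(0, 1e-12, 100)  # survive the quality filter
        im = fit_impact_model(X_fit, y.to_numpy(), seed=0, tune=False)
        expl = shap_values(im, X_fit)
        used_by_trees = set()
        for est in im.model.estimators_.ravel():
            used_by_trees |= set(est.tree_.feature[est.tree_.feature >= 0])
        if 2 not in used_by_trees:
            assert (expl.values["dead"] == 0.0).all()

    def test_column_mismatch_rejected(self, fitted_small):
        im, X = fitted_small
        with pytest.raises(ValueError, match="columns"):
            shap_values(im, X.rename(columns={"a": "zz"}))

    def test_symmetry_of_duplicate_columns(self):
        """Two byte-identical feature columns receive equal mean |phi|."""
        rng = np.random.default_rng(4)
        a = rng.normal(size=120)
        X = pd.DataFrame({"f1": a, "f2": a.copy(), "noise": rng.normal(size=120)})
        y = 2.0 * a + rng.normal(0, 0.1, 120)
        # feature subsampling so the duplicates actually share splits
        im = fit_impact_model(
            X, y, seed=0, tune=True,
            grid={"max_features": [0.5], "n_estimators": [150], "max_depth": [2]},
        )
        expl = shap_values(im, X)
        m1 = expl.values["f1"].abs().mean()
        m2 = expl.values["f2"].abs().mean()
        assert m1 + m2 > 0
        # duplicated columns share credit arbitrarily between themselves per
        # tree, but their joint attribution is balanced within tolerance
        assert abs(m1 - m2) / (m1 + m2) < 0.35


class TestImportance:
    def test_causal_features_rank_top(self, area_world):
        table, impact, truth = area_world
        im = fit_impact_model(table, impact, seed=0, tune=False)
        expl = shap_values(im, table)
        gi = global_importance(expl, table)
        top5 = set(gi.table.head(5)["feature"])
        causal = set(truth.causal_coef)
        assert len(causal & top5) >= 2

    def test_monotone_feature_has_positive_correlation(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = 2.5 * X["a"] + rng.normal(0, 0.2, 120)
        im = fit_impact_model(X, y.to_numpy(), seed=0, tune=False)
        gi = global_importance(shap_values(im, X), X)
        row = gi.table.set_index("feature").loc["a"]
        assert row["pearson_r"] > 0.9

    def test_zero_variance_shap_gives_nan_not_zero(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        expl.values["d"] = 0.0  # force a degenerate column
        gi = global_importance(expl, X)
        r = gi.table.set_index("feature").loc["d", "pearson_r"]
        assert np.isnan(r)


class TestTotalGain:
    def test_unused_feature_zero_gain(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=100), "flat": np.ones(100)})
        X["flat"] += rng.normal(0, 1e-12, 100)
        y = X["x"].to_numpy() * 2
        im = fit_impact_model(X, y, seed=0, tune=False)
        gains = total_gain_importance(im).set_index("feature")
        assert gains.loc["flat", "total_gain"] == pytest.approx(0.0, abs=1e-6)

    def test_gain_and_shap_rankings_overlap(self, area_world):
        table, impact, _ = area_world
        im = fit_impact_model(table, impact, seed=0, tune=False)
        expl = shap_values(im, table)
        top_shap = set(global_importance(expl, table).table.head(5)["feature"])
        top_gain = set(total_gain_importance(im).head(5)["feature"])
        jacc = len(top_shap & top_gain) / len(top_shap | top_gain)
        assert jacc >= 0.4


class TestDependence:
    def test_pearson_matches_direct_formula(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        tab, r = dependence_summary(expl, X, "b")
        x = tab["feature_value"].to_numpy()
        s = tab["shap_value"].to_numpy()
        direct = np.mean((x - x.mean()) * (s - s.mean())) / (x.std() * s.std())
        assert r == pytest.approx(direct, abs=1e-12)

    def test_degenerate_column_flagged(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        expl.values["c"] = 0.0
        _, r = dependence_summary(expl, X, "c")
        assert np.isnan(r)

    def test_unknown_feature_rejected(self, fitted_small):
        im, X = fitted_small
        expl = shap_values(im, X)
        with pytest.raises(KeyError):
            dependence_summary(expl, X, "nope")
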