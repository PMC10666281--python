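"""Gradient-boosted trees on areal impacts, explained with Shapley values.

The model maps areal spatial features to the estimated pollution impact
(absolute µg/m³ or relative percentage points). Shapley values are computed
exactly for tree ensembles: within one tree the value function v(S) is the
cover-weighted conditional expectation by tree traversal (descend by the
instance's feature value when the split feature is in S, otherwise average
both children weighted by their training cover), and the Shapley sum is
enumerated over subsets of the features each tree actually uses (features
absent from a tree are dummy players and receive zero from it). This is
polynomial in practice because boosted trees are shallow; it satisfies
local accuracy — base value plus the per-feature contributions equals the
model prediction — to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [2, 3],
    "learning_rate": [0.05, 0.1],
}


def quality_filter(
    features: pd.DataFrame, max_missing: float = 0.2
) -> pd.DataFrame:
    """Drop feature columns with > ``max_missing`` missing rows or zero
    variance (stand-in for routine covariate QA)."""
    keep = []
    for col in features.columns:
        s = features[col]
        if s.isna().mean() > max_missing:
            continue
        if s.dropna().nunique() <= 1:
            continue
        keep.append(col)
    return features[keep]


@dataclass
class ImpactModel:
    model: GradientBoostingRegressor
    feature_names: list
    cv_report: dict
    X_train: np.ndarray


def fit_impact_model(
    features: pd.DataFrame,
    target: np.ndarray,
    seed: int = 0,
    grid: dict | None = None,
    tune: bool = True,
    min_areas: int = 50,
) -> ImpactModel:
    """Boosted regression trees of areal impacts on spatial features.

    Hyperparameters (depth, learning rate, trees) are tuned by 3-fold CV
    over :data:`DEFAULT_GRID`; the report carries CV RMSE and R².
    """
    target = np.asarray(target, dtype=float)
    if len(features) < min_areas:
        raise ValueError(f"{len(features)} areas; need >= {min_areas}")
    bad = np.flatnonzero(~np.isfinite(target))
    if len(bad):
        ids = features.index[bad].tolist()[:10]
        raise ValueError(f"non-finite target for areas {ids}")
    feats = quality_filter(features)
    X = feats.to_numpy(dtype=float)
    cv = KFold(n_splits=3, shuffle=True, random_state=seed)
    if tune:
        search = GridSearchCV(
            GradientBoostingRegressor(random_state=seed),
            grid or DEFAULT_GRID,
            cv=cv,
            scoring="neg_root_mean_squared_error",
            n_jobs=1,
        )
        search.fit(X, target)
        model = search.best_estimator_
        rmse = -float(search.best_score_)
        params = search.best_params_
    else:
        model = GradientBoostingRegressor(random_state=seed, max_depth=3)
        rmse = -float(
            cross_val_score(
                model, X, target, cv=cv, scoring="neg_root_mean_squared_error"
            ).mean()
        )
        model.fit(X, target)
        params = model.get_params()
    r2 = float(
        cross_val_score(model, X, target, cv=cv, scoring="r2").mean()
    )
    if tune:
        model.fit(X, target)  # refit on all areas with the chosen params
    return ImpactModel(
        model=model,
        feature_names=list(feats.columns),
        cv_report={"cv_rmse": rmse, "cv_r2": r2, "params": params, "n_areas": len(X)},
        X_train=X,
    )


# ---------------------------------------------------------------------------
# Exact tree Shapley

def _tree_cond_exp(tree, X: np.ndarray, in_S: np.ndarray) -> np.ndarray:
    """Cover-weighted conditional expectation of one tree for every row of X,
    conditioning on the features flagged in ``in_S``."""
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    value = tree.value.reshape(-1)
    wn = tree.weighted_n_node_samples
    n = len(X)
    out = np.zeros(n)

    def rec(node: int, rows: np.ndarray, weight: np.ndarray) -> None:
        if left[node] == -1:  # leaf
            out[rows] += weight * value[node]
            return
        f = feat[node]
        if in_S[f]:
            go_left = X[rows, f] <= thr[node]
            if go_left.any():
                rec(left[node], rows[go_left], weight[go_left])
            if (~go_left).any():
                rec(right[node], rows[~go_left], weight[~go_left])
        else:
            wl = wn[left[node]] / wn[node]
            rec(left[node], rows, weight * wl)
            rec(right[node], rows, weight * (1.0 - wl))

    rec(0, np.arange(n), np.ones(n))
    return out


def _tree_shapley(tree, X: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values (n_rows × n_features) for one regression tree.

    Enumerates subsets of the features the tree uses; unused features are
    dummies with value exactly 0, so restricting the enumeration to the
    used set leaves the other values unchanged.
    """
    used = sorted(set(tree.feature[tree.feature >= 0].tolist()))
    phi = np.zeros((len(X), n_features))
    if not used:
        return phi
    if len(used) > 14:
        raise ValueError(f"tree uses {len(used)} features; exact enumeration too large")
    m = len(used)
    cache: dict[frozenset, np.ndarray] = {}

    def v(subset: frozenset) -> np.ndarray:
        if subset not in cache:
            in_S = np.zeros(n_features, dtype=bool)
            in_S[list(subset)] = True
            cache[subset] = _tree_cond_exp(tree, X, in_S)
        return cache[subset]

    for i in used:
        others = [f for f in used if f != i]
        for k in range(m):
            w = factorial(k) * factorial(m - k - 1) / factorial(m)
            for S in combinations(others, k):
                fs = frozenset(S)
                phi[:, i] += w * (v(fs | {i}) - v(fs))
    return phi


@dataclass
class ShapExplanation:
    """Additive per-feature contributions in model-output units."""

    values: pd.DataFrame  # area × feature
    base_value: float
    predictions: np.ndarray
    feature_names: list


def shap_values(im: ImpactModel, features: pd.DataFrame) -> ShapExplanation:
    """Exact Shapley explanation of the boosted ensemble on ``features``.

    base_value + row-sum of contributions equals the model prediction for
    every area (local accuracy, machine precision).
    """
    if list(features.columns) != im.feature_names:
        missing = set(im.feature_names) ^ set(features.columns)
        raise ValueError(f"feature columns do not match training columns: {missing}")
    X = features.to_numpy(dtype=float)
    gbr = im.model
    lr = gbr.learning_rate
    p = X.shape[1]
    phi = np.zeros((len(X), p))
    base = float(gbr.init_.constant_.ravel()[0])
    for est in gbr.estimators_.ravel():
        t = est.tree_
        phi += lr * _tree_shapley(t, X, p)
        base += lr * float(
            _tree_cond_exp(t, X[:1], np.zeros(p, dtype=bool))[0]
        )
    preds = gbr.predict(X)
    return ShapExplanation(
        values=pd.DataFrame(phi, index=features.index, columns=im.feature_names),
        base_value=base,
        predictions=preds,
        feature_names=im.feature_names,
    )


@dataclass
class GlobalImportance:
    table: pd.DataFrame  # feature, mean_abs_shap, pearson_r, rank


def global_importance(
    expl: ShapExplanation, features: pd.DataFrame, top_k: int = 20
) -> GlobalImportance:
    """Mean |contribution| per feature plus the Pearson correlation between
    feature values and contributions; ranked descending by importance.

    A zero-variance contribution column gets correlation NaN (undefined),
    never 0.
    """
    rows = []
    for col in expl.feature_names:
        sv = expl.values[col].to_numpy()
        fv = features[col].to_numpy(dtype=float)
        if np.std(sv) < 1e-15 or np.std(fv) < 1e-15:
            r = float("nan")
        else:
            r = float(stats.pearsonr(fv, sv)[0])
        rows.append({"feature": col, "mean_abs_shap": float(np.mean(np.abs(sv))), "pearson_r": r})
    tab = pd.DataFrame(rows).sort_values("mean_abs_shap", ascending=False)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return GlobalImportance(table=tab.head(top_k).reset_index(drop=True))


def total_gain_importance(im: ImpactModel) -> pd.DataFrame:
    """Per-feature total gain: summed squared-error reduction over every
    split that uses the feature, across all trees."""
    p = len(im.feature_names)
    gain = np.zeros(p)
    for est in im.model.estimators_.ravel():
        t = est.tree_
        for node in range(t.node_count):
            if t.children_left[node] == -1:
                continue
            l, r = t.children_left[node], t.children_right[node]
            reduction = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[l] * t.impurity[l]
                - t.weighted_n_node_samples[r] * t.impurity[r]
            )
            gain[t.feature[node]] += reduction
    tab = pd.DataFrame({"feature": im.feature_names, "total_gain": gain})
    return tab.sort_values("total_gain", ascending=False).reset_index(drop=True)


def dependence_summary(
    expl: ShapExplanation, features: pd.DataFrame, feature_name: str
) -> tuple[pd.DataFrame, float]:
    """(feature value, contribution) pairs per area and their Pearson R.

    R is NaN (flagged undefined) when the contribution column is constant.
    """
    if feature_name not in expl.feature_names:
        raise KeyError(f"unknown feature {feature_name!r}")
    fv = features[feature_name].to_numpy(dtype=float)
    sv = expl.values[feature_name].to_numpy()
    tab = pd.DataFrame({"feature_value": fv, "shap_value": sv}, index=features.index)
    if np.std(sv) < 1e-15 or np.std(fv) < 1e-15:
        return tab, float("nan")
    return tab, float(stats.pearsonr(fv, sv)[0])
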