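"""Residual kriging: regression, variogram fitting, kriging system, mapping."""

import numpy as np
import pandas as pd
import pytest

from aqcausal.spatial import (
    CollinearityError,
    VariogramModel,
    empirical_variogram,
    fit_mapping_regression,
    fit_variogram,
    krige,
    map_impacts,
)
from aqcausal.synthetic import SimConfig, exponential_field, generate_area_impacts


class TestRegression:
    def test_exact_linear_impacts_leave_zero_residuals(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        y = 2.0 + 3.0 * X["a"] - 1.5 * X["b"]
        beta, resid = fit_mapping_regression(y.to_numpy(), X)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)
        assert beta["intercept"] == pytest.approx(2.0)
        assert beta["a"] == pytest.approx(3.0)

    def test_intercept_only_residuals_are_centered(self, rng):
        y = rng.normal(10, 2, 15)
        X = pd.DataFrame(index=range(15))
        beta, resid = fit_mapping_regression(y, X)
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-10)

    def test_three_site_system_by_hand(self):
        """Normal equations solved by hand for 3 points, 1 covariate —
        padded to meet the sample-size guard with exact duplicates."""
        x = np.array([0.0, 1.0, 2.0] * 4)
        y = np.array([1.0, 3.0, 4.0] * 4)
        # hand solution: slope = Sxy/Sxx = 1.5, intercept = ybar - 1.5*xbar
        beta, _ = fit_mapping_regression(y, pd.DataFrame({"x": x}))
        assert beta["x"] == pytest.approx(1.5)
        assert beta["intercept"] == pytest.approx(8 / 3 - 1.5)

    def test_collinear_columns_named(self, rng):
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(CollinearityError, match="b"):
            fit_mapping_regression(rng.normal(size=20), X)


class TestVariogram:
    def test_pure_nugget_for_iid_residuals(self, rng):
        coords = rng.uniform(0, 50, size=(400, 2))
        resid = rng.normal(0, 1, 400)
        vgm = fit_variogram(resid, coords)
        # either negligible structure or structure at negligible range
        assert (vgm.nugget > 0.6 * np.var(resid)) or (vgm.range_ < 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_known_exponential_field_range_recovered(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 60, size=(300, 2))
        field = exponential_field(coords, sill=1.0, range_km=10.0, rng=rng)
        vgm = fit_variogram(field, coords)
        assert 5.0 <= vgm.range_ <= 20.0  # within factor 2

    def test_constant_residuals_zero_sill(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(30, 2))
        vgm = fit_variogram(np.full(30, 3.3), coords)
        assert vgm.psill == 0.0 and vgm.nugget == 0.0

    def test_identical_distances_rejected(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            empirical_variogram(np.array([1.0, 2.0]), coords)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            VariogramModel("exponential", nugget=-1.0, psill=1.0, range_=1.0, bins=None)


class TestKrige:
    def _vgm(self, nugget=0.0):
        return VariogramModel("exponential", nugget=nugget, psill=2.0,
                              range_=5.0, bins=None)

    def test_exactness_at_data_points_with_zero_nugget(self, rng):
        coords = rng.uniform(0, 10, size=(6, 2))
        vals = rng.normal(size=6)
        preds, var = krige(vals, coords, self._vgm(), coords)
        np.testing.assert_allclose(preds, vals, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_weights_match_direct_augmented_solve(self):
        """5 hand-placed points: the kriging prediction equals the
        brute-force solve of [[C, 1],[1', 0]] built independently."""
        coords = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 1]], dtype=float)
        vals = np.array([1.0, 2.0, 0.5, 1.5, 1.2])
        target = np.array([[2.0, 2.0]])
        vgm = self._vgm(nugget=0.3)
        preds, var = krige(vals, coords, vgm, target)
        # independent construction
        sill = 2.3
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        C = np.where(d == 0, sill, sill - (0.3 + 2.0 * (1 - np.exp(-d / 5.0))))
        A = np.zeros((6, 6))
        A[:5, :5] = C
        A[5, :5] = A[:5, 5] = 1.0
        d0 = np.sqrt(((target - coords) ** 2).sum(-1))
        c0 = sill - (0.3 + 2.0 * (1 - np.exp(-d0 / 5.0)))
        sol = np.linalg.solve(A, np.concatenate([c0, [1.0]]))
        w, mu = sol[:5], sol[5]
        assert preds[0] == pytest.approx(w @ vals, abs=1e-10)
        assert var[0] == pytest.approx(sill - w @ c0 - mu, abs=1e-10)

    def test_weights_sum_to_one_everywhere(self, rng):
        coords = rng.uniform(0, 20, size=(8, 2))
        vals = rng.normal(size=8)
        targets = rng.uniform(0, 20, size=(30, 2))
        # constant-shift trick: adding c to all data must add c to predictions
        p1, _ = krige(vals, coords, self._vgm(0.5), targets)
        p2, _ = krige(vals + 5.0, coords, self._vgm(0.5), targets)
        np.testing.assert_allclose(p2 - p1, 5.0, atol=1e-9)

    def test_variance_grows_with_distance_on_transect(self):
        coords = np.array([[0.0, 0.0]])
        vals = np.array([1.0])
        # single site: OK system is degenerate with one point; use two
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        vals = np.array([1.0, 2.0])
        targets = np.c_[np.linspace(1.5, 15, 20), np.zeros(20)]
        _, var = krige(vals, coords, self._vgm(), targets)
        assert (np.diff(var) >= -1e-9).all()

    def test_duplicate_coordinates_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            krige(np.ones(3), coords, self._vgm(), np.array([[0.5, 0.5]]))


class TestMapImpacts:
    def _world(self, seed=0, n_sites=25):
        rng = np.random.default_rng(seed)
        site_coords = rng.uniform(0, 40, size=(n_sites, 2))
        m = 10
        ax = np.arange(m) * 4.0 + 2.0
        gx, gy = np.meshgrid(ax, ax)
        grid_coords = np.c_[gx.ravel(), gy.ravel()]
        cov_fn = lambda xy: pd.DataFrame({"urban": 10 - 0.3 * xy[:, 0],
                                          "traffic": 0.2 * xy[:, 1]})
        return rng, site_coords, grid_coords, cov_fn

    def test_single_area_mean_equals_grid_mean(self):
        rng, sc, gc, cov_fn = self._world()
        truth = lambda xy, cov: -5 + 0.8 * cov["urban"] - 0.5 * cov["traffic"]
        site_cov = cov_fn(sc)
        impacts = truth(sc, site_cov).to_numpy() + rng.normal(0, 0.2, len(sc))
        surface, areal = map_impacts(
            impacts, site_cov, sc, cov_fn(gc), gc,
            cell_area_ids=np.zeros(len(gc), dtype=int),
        )
        assert areal["impact"].iloc[0] == pytest.approx(surface.grid["value"].mean())

    def test_constant_impacts_give_constant_surface(self):
        _, sc, gc, cov_fn = self._world(1)
        impacts = np.full(len(sc), -4.2)
        surface, _ = map_impacts(impacts, cov_fn(sc), sc, cov_fn(gc), gc)
        np.testing.assert_allclose(surface.grid["value"], -4.2, atol=1e-8)

    def test_decomposition_reassembles(self, rng):
        _, sc, gc, cov_fn = self._world(2)
        impacts = rng.normal(-5, 1, len(sc))
        surface, _ = map_impacts(impacts, cov_fn(sc), sc, cov_fn(gc), gc)
        np.testing.assert_allclose(
            surface.grid["value"],
            surface.grid["regression"] + surface.grid["kriged"],
            atol=1e-10,
        )

    def test_missing_area_raises(self):
        _, sc, gc, cov_fn = self._world(3)
        impacts = np.zeros(len(sc))
        with pytest.raises(ValueError, match="zero assigned"):
            map_impacts(
                impacts, cov_fn(sc), sc, cov_fn(gc), gc,
                cell_area_ids=np.zeros(len(gc), dtype=int),
                expected_area_ids=np.array([0, 1]),
            )

    def test_residual_kriging_beats_regression_alone(self):
        """Truth = linear(covariates) + exponential field: adding kriged
        residuals lowers grid RMSE vs regression-only in >= 8/10 seeds."""
        wins = 0
        for seed in range(10):
            rng, sc, gc, cov_fn = self._world(100 + seed, n_sites=40)
            all_xy = np.vstack([sc, gc])
            field = exponential_field(all_xy, sill=1.5, range_km=12.0, rng=rng)
            site_cov, grid_cov = cov_fn(sc), cov_fn(gc)
            lin = lambda cov: -5 + 0.8 * cov["urban"] - 0.5 * cov["traffic"]
            site_truth = lin(site_cov).to_numpy() + field[: len(sc)]
            grid_truth = lin(grid_cov).to_numpy() + field[len(sc):]
            surface, _ = map_impacts(site_truth, site_cov, sc, grid_cov, gc)
            rmse_full = np.sqrt(np.mean((surface.grid["value"] - grid_truth) ** 2))
            rmse_reg = np.sqrt(np.mean((surface.grid["regression"] - grid_truth) ** 2))
            wins += rmse_full < rmse_reg
        assert wins >= 8
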