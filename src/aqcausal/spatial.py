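"""Residual kriging: linear regression on spatial covariates plus ordinary
kriging of its residuals, interpolated to a grid and averaged to areas.

Coordinates are planar kilometres; no geodesy. The variogram is fit by
weighted least squares (weights = pair counts) to a method-of-moments
empirical semivariogram; the ordinary-kriging system enforces unit-sum
weights through a Lagrange multiplier and is exact at data locations when
the nugget is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class CollinearityError(ValueError):
    pass


def fit_mapping_regression(
    site_impacts: np.ndarray, site_covariates: pd.DataFrame
) -> tuple[pd.Series, np.ndarray]:
    """OLS of site impacts on covariates (intercept added).

    Returns the named coefficient vector and the per-site residuals. A
    rank-deficient design raises :class:`CollinearityError` naming the
    dependent columns.
    """
    y = np.asarray(site_impacts, dtype=float)
    X = np.column_stack([np.ones(len(y)), site_covariates.to_numpy(dtype=float)])
    names = ["intercept"] + list(site_covariates.columns)
    if len(y) < X.shape[1] + 4:
        raise ValueError(
            f"{len(y)} sites for {X.shape[1] - 1} covariates; need >= p + 5"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank
        bad, r = [], 0
        for k in range(X.shape[1]):
            rk = np.linalg.matrix_rank(X[:, : k + 1])
            if rk == r:
                bad.append(names[k])
            r = rk
        raise CollinearityError(f"design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(beta, index=names), resid


@dataclass
class VariogramModel:
    """Fitted semivariogram γ(d) = nugget + psill * f(d / range)."""

    family: str  # exponential | spherical
    nugget: float
    psill: float
    range_: float
    bins: pd.DataFrame  # empirical variogram: distance, semivariance, n_pairs

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters must be non-negative, range > 0")

    def gamma(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.family == "exponential":
            struct = 1.0 - np.exp(-d / self.range_)
        elif self.family == "spherical":
            h = np.clip(d / self.range_, 0, 1)
            struct = 1.5 * h - 0.5 * h**3
        else:
            raise ValueError(f"unknown family {self.family!r}")
        out = self.nugget + self.psill * struct
        return np.where(d == 0, 0.0, out)  # gamma(0) = 0 by definition

    def covariance(self, d: np.ndarray) -> np.ndarray:
        """C(d) = sill − γ(d) with the nugget active only at d = 0."""
        d = np.asarray(d, dtype=float)
        sill = self.nugget + self.psill
        return np.where(d == 0, sill, sill - self.gamma(d))


def empirical_variogram(
    values: np.ndarray, coords: np.ndarray, n_bins: int = 12, max_dist: float | None = None
) -> pd.DataFrame:
    """Method-of-moments semivariogram on equal-width distance bins."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    if np.allclose(dist, dist[0]):
        raise ValueError("all pairwise distances identical; variogram undefined")
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    gam = sq[iu]
    if max_dist is None:
        max_dist = float(dist.max()) / 2
    edges = np.linspace(0, max_dist, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dist > lo) & (dist <= hi)
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "distance": float(dist[mask].mean()),
                "semivariance": float(gam[mask].mean()),
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    family: str = "exponential",
    n_bins: int = 12,
    max_dist: float | None = None,
) -> VariogramModel:
    """WLS fit of the chosen family to the empirical variogram.

    Weights are pair counts. Parameters are bounded non-negative; the
    starting point uses the sample variance and a third of the maximum
    bin distance.
    """
    if len(residuals) < 10:
        raise ValueError("need >= 10 points to fit a variogram")
    bins = empirical_variogram(residuals, coords, n_bins=n_bins, max_dist=max_dist)
    d = bins["distance"].to_numpy()
    g = bins["semivariance"].to_numpy()
    w = np.sqrt(bins["n_pairs"].to_numpy(dtype=float))
    var = float(np.var(residuals))
    if var < 1e-15:
        return VariogramModel(family, 0.0, 0.0, max(d.max(), 1e-6), bins)

    def resid_fn(p):
        vm = VariogramModel(family, p[0], p[1], p[2], bins)
        return w * (vm.gamma(d) - g)

    x0 = np.array([0.1 * var, 0.9 * var, max(d.max() / 3, 1e-3)])
    sol = least_squares(
        resid_fn, x0, bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]), method="trf"
    )
    return VariogramModel(family, *map(float, sol.x), bins)


def krige(
    residuals: np.ndarray,
    coords: np.ndarray,
    vgm: VariogramModel,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of ``residuals`` at ``targets``.

    Solves the augmented system [[C, 1], [1ᵀ, 0]] [w; μ] = [c₀; 1] per
    target; returns predictions and kriging variances. Exact (variance 0)
    at data locations when the nugget is zero.
    """
    residuals = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(residuals)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    off_diag = d[np.triu_indices(n, k=1)]
    if np.any(off_diag < 1e-12):
        raise ValueError("duplicate coordinates make the kriging matrix singular")
    C = vgm.covariance(d)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    sill = vgm.nugget + vgm.psill
    try:
        lu = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging matrix") from exc
    d0 = np.sqrt(((targets[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    # covariance between target and data; at d=0 the target IS the datum, so
    # the full sill (incl. nugget) applies, giving exactness for nugget-free models
    c0 = np.where(d0 == 0, sill, sill - vgm.gamma(d0))
    rhs = np.column_stack([c0, np.ones(len(targets))])
    sol = rhs @ lu.T
    w = sol[:, :n]
    mu = sol[:, n]
    preds = w @ residuals
    variances = np.maximum(sill - (w * c0).sum(axis=1) - mu, 0.0)
    return preds, variances


@dataclass
class GridSurface:
    """Predicted impact surface on grid-cell centers."""

    grid: pd.DataFrame  # x_km, y_km, regression, kriged, value, variance


def map_impacts(
    site_impacts: np.ndarray,
    site_covariates: pd.DataFrame,
    site_coords: np.ndarray,
    grid_covariates: pd.DataFrame,
    grid_coords: np.ndarray,
    cell_area_ids: np.ndarray | None = None,
    expected_area_ids: np.ndarray | None = None,
    variogram_family: str = "exponential",
) -> tuple[GridSurface, pd.DataFrame | None]:
    """Site impacts → grid surface (regression + kriged residuals) → areas.

    ``grid_covariates`` columns must match ``site_covariates``; areal values
    are unweighted means over cells sharing an ``area_id`` (cells are
    equal-area). Returns the surface and, when ``cell_area_ids`` is given,
    the areal impact table.
    """
    beta, resid = fit_mapping_regression(site_impacts, site_covariates)
    Xg = np.column_stack(
        [np.ones(len(grid_covariates)), grid_covariates[site_covariates.columns].to_numpy()]
    )
    reg_part = Xg @ beta.to_numpy()
    if np.allclose(resid, 0.0):
        kriged = np.zeros(len(grid_coords))
        variance = np.zeros(len(grid_coords))
    elif len(resid) < 10:
        import warnings

        warnings.warn(
            f"only {len(resid)} sites: too few to fit a variogram; "
            "falling back to regression-only mapping",
            stacklevel=2,
        )
        kriged = np.zeros(len(grid_coords))
        variance = np.full(len(grid_coords), float(np.var(resid)))
    else:
        vgm = fit_variogram(resid, site_coords, family=variogram_family)
        kriged, variance = krige(resid, site_coords, vgm, grid_coords)
    grid = pd.DataFrame(
        {
            "x_km": grid_coords[:, 0],
            "y_km": grid_coords[:, 1],
            "regression": reg_part,
            "kriged": kriged,
            "value": reg_part + kriged,
            "variance": variance,
        }
    )
    surface = GridSurface(grid=grid)
    if cell_area_ids is None:
        return surface, None
    cell_area_ids = np.asarray(cell_area_ids)
    areal = (
        grid.assign(area_id=cell_area_ids)
        .groupby("area_id")["value"]
        .mean()
        .rename("impact")
        .reset_index()
    )
    if expected_area_ids is not None:
        missing = set(expected_area_ids) - set(areal["area_id"])
        if missing:
            raise ValueError(f"areas with zero assigned cells: {sorted(missing)}")
    return surface, areal
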