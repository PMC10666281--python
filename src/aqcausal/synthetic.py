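"""Synthetic monitoring-network generator with known ground truth.

Emulates the statistical structure of an urban air-quality network around
an intervention with a known start date T0: hourly concentrations driven by
weather and seasonality, a long-term downward trend, a site-level
multiplicative step effect at T0, plus areal feature tables whose "impact"
surface is a known sparse function of a few features and a spatially
correlated field.

Everything is deterministic given ``SimConfig.seed``. The generator returns
a ground-truth record holding every latent component so downstream stages
can be tested against construction rather than against themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

WEATHER_VARS = (
    "temperature",
    "wind_speed",
    "wind_direction",
    "pressure",
    "relative_humidity",
    "rainfall",
    "monin_obukhov",
)

# (mean, diurnal amplitude, annual amplitude, AR(1) innovation sd) per variable
_WEATHER_PARAMS = {
    "temperature": (11.0, 3.0, 7.0, 0.8),  # degC
    "wind_speed": (4.5, 0.8, 1.0, 0.7),  # m/s
    "wind_direction": (200.0, 0.0, 30.0, 25.0),  # deg
    "pressure": (1013.0, 0.5, 4.0, 1.5),  # hPa
    "relative_humidity": (75.0, 8.0, 6.0, 4.0),  # %
    "rainfall": (0.08, 0.02, 0.04, 0.15),  # mm/h, clipped at 0
    "monin_obukhov": (20.0, 40.0, 10.0, 30.0),  # m
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """World definition for one synthetic monitoring network.

    Defaults state a realistic mid-sized network: a multi-year hourly
    record with the intervention in the final spring, site effects of
    order −10%, a slow downward trend of 2%/year, and hourly log-scale
    noise of 0.3 (the residual scatter a weather model typically leaves
    on urban NO2).
    """

    n_sites: int = 6
    site_types: Sequence[str] | None = None  # roadside/background per site
    start: str = "2019-01-01"
    end: str = "2020-12-31"
    t0: str = "2020-03-23"  # national lockdown start
    true_tau: Sequence[float] | float = -0.10  # relative step effect per site
    trend_slope: float = -0.02  # log-concentration per year
    noise_sd: float = 0.30  # hourly log-scale sigma
    baseline_log: float = float(np.log(35.0))  # ~35 ug/m3 urban NO2
    weather_ar1: float = 0.9
    missing_frac: float = 0.0
    ramp_days: int = 0  # 0 = pure step; >0 = linear ramp over the margin
    n_areas: int = 200
    domain_km: float = 40.0  # square city domain side
    seed: int = 0

    def __post_init__(self) -> None:
        self.start_ts = pd.Timestamp(self.start)
        self.end_ts = pd.Timestamp(self.end)
        self.t0_ts = pd.Timestamp(self.t0)
        if not (self.start_ts < self.t0_ts < self.end_ts):
            raise ConfigError(
                f"need start < T0 < end, got {self.start} / {self.t0} / {self.end}"
            )
        if self.site_types is None:
            self.site_types = tuple(
                "roadside" if i % 2 else "background" for i in range(self.n_sites)
            )
        if len(self.site_types) != self.n_sites:
            raise ConfigError("site_types length must equal n_sites")
        taus = self.tau_vector()
        if np.any(taus <= -1):
            raise ConfigError("true_tau must be > -1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.missing_frac < 1:
            raise ConfigError("missing_frac must be in [0, 1)")

    def tau_vector(self) -> np.ndarray:
        if np.isscalar(self.true_tau):
            return np.full(self.n_sites, float(self.true_tau))
        taus = np.asarray(self.true_tau, dtype=float)
        if taus.shape != (self.n_sites,):
            raise ConfigError("true_tau vector must have one entry per site")
        return taus

    def hours(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_ts, self.end_ts + pd.Timedelta(hours=23), freq="h")


def _seasonal(doy: np.ndarray, phase: float = 15.0) -> np.ndarray:
    return np.cos(2 * np.pi * (doy - phase) / 365.25)


def generate_weather(config: SimConfig) -> pd.DataFrame:
    """Seven hourly weather series with diurnal + annual cycles and AR(1) noise.

    Returns a wide frame indexed by timestamp with one column per variable in
    :data:`WEATHER_VARS`. Wind direction is wrapped to [0, 360); rainfall is
    clipped at zero.
    """
    idx = config.hours()
    n = len(idx)
    hour = idx.hour.to_numpy()
    doy = idx.dayofyear.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rho = config.weather_ar1
    out = {}
    for var in WEATHER_VARS:
        mean, diurnal_amp, annual_amp, innov_sd = _WEATHER_PARAMS[var]
        cycle = (
            mean
            - annual_amp * _seasonal(doy)  # winter low for temperature-like shape
            + diurnal_amp * np.cos(2 * np.pi * (hour - 14) / 24)
        )
        eps = rng.normal(0.0, innov_sd, n)
        ar = np.empty(n)
        # stationary start so the lag-1 autocorrelation matches rho from t=0
        ar[0] = eps[0] / np.sqrt(1 - rho**2) if rho < 1 else eps[0]
        for t in range(1, n):
            ar[t] = rho * ar[t - 1] + eps[t]
        series = cycle + ar
        if var == "wind_direction":
            series = np.mod(series, 360.0)
        elif var == "rainfall":
            series = np.clip(series, 0.0, None)
        elif var in ("wind_speed", "relative_humidity"):
            series = np.clip(series, 0.0, None)
        out[var] = series
    return pd.DataFrame(out, index=idx)


def weather_effect(weather: pd.DataFrame) -> np.ndarray:
    """Documented nonlinear weather→log-concentration transfer g.

    Plausible dispersion physics, fully known to the tests:

    * dilution by wind: ``+0.8/(1 + ws)`` (high wind → low concentration),
    * temperature U-shape: ``+0.002*(T - 12)**2`` (cold heating emissions,
      hot photochemistry / boundary-layer effects),
    * stability: ``+0.1*tanh(-L/50)`` of the Monin–Obukhov length (stable
      nights trap pollutants),
    * washout: ``-0.05*min(rain, 2)``.

    Centered to near-zero mean so the baseline stays interpretable.
    """
    g = (
        0.8 / (1.0 + weather["wind_speed"].to_numpy())
        + 0.002 * (weather["temperature"].to_numpy() - 12.0) ** 2
        + 0.1 * np.tanh(-weather["monin_obukhov"].to_numpy() / 50.0)
        - 0.05 * np.minimum(weather["rainfall"].to_numpy(), 2.0)
    )
    return g - 0.25  # rough centering constant


def _seasonal_log(idx: pd.DatetimeIndex) -> np.ndarray:
    """Hour-of-day, day-of-week and day-of-year harmonics on the log scale."""
    hour = idx.hour.to_numpy()
    dow = idx.dayofweek.to_numpy()
    doy = idx.dayofyear.to_numpy()
    return (
        0.25 * np.cos(2 * np.pi * (hour - 8) / 24)  # rush-hour shape
        + 0.08 * np.cos(4 * np.pi * (hour - 8) / 24)
        - 0.10 * (dow >= 5)  # weekend dip
        + 0.10 * _seasonal(doy)
    )


def step_profile(idx: pd.DatetimeIndex, config: SimConfig, tau: float) -> np.ndarray:
    """Log-scale intervention profile: ln(1+tau) after T0.

    Pure step by default; with ``ramp_days > 0`` the step phases in linearly
    over ``[T0, T0 + ramp_days)`` to exercise the donut design.
    """
    days_from_t0 = (idx - config.t0_ts) / pd.Timedelta(days=1)
    full = np.log1p(tau)
    if config.ramp_days <= 0:
        return np.where(days_from_t0 >= 0, full, 0.0)
    frac = np.clip(days_from_t0 / config.ramp_days, 0.0, 1.0)
    return np.where(days_from_t0 >= 0, full * frac, 0.0)


def generate_site_series(
    config: SimConfig, weather: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Hourly concentrations for every site plus the ground-truth record.

    ln(conc) = baseline + g(weather) + seasonal harmonics + trend + step + noise.

    Returns
    -------
    conc : DataFrame indexed by timestamp, one column per site id; missing
        hours (if ``missing_frac > 0``) are NaN, never zero.
    truth : dict with every latent component and per-site metadata.
    """
    idx = weather.index
    if idx[0] > config.start_ts or idx[-1] < config.end_ts:
        raise ConfigError("weather does not cover the configured period")
    g = weather_effect(weather)
    seas = _seasonal_log(idx)
    years = (idx - config.start_ts) / pd.Timedelta(days=365.25)
    trend = config.trend_slope * years.to_numpy()
    taus = config.tau_vector()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    site_ids = [f"site{i:02d}" for i in range(config.n_sites)]
    cols = {}
    steps = {}
    for i, sid in enumerate(site_ids):
        step = step_profile(idx, config, taus[i])
        noise = rng.normal(0.0, config.noise_sd, len(idx)) if config.noise_sd > 0 else 0.0
        site_offset = 0.3 if config.site_types[i] == "roadside" else 0.0
        logc = config.baseline_log + site_offset + g + seas + trend + step + noise
        vals = np.exp(logc)
        if config.missing_frac > 0:
            gaps = rng.random(len(idx)) < config.missing_frac
            vals = np.where(gaps, np.nan, vals)
        cols[sid] = vals
        steps[sid] = step
    conc = pd.DataFrame(cols, index=idx)
    # site coordinates on the planar km domain
    coord_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    coords = coord_rng.uniform(0, config.domain_km, size=(config.n_sites, 2))
    meta = pd.DataFrame(
        {
            "site_id": site_ids,
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
            "type": list(config.site_types),
        }
    )
    truth = {
        "site_ids": site_ids,
        "true_tau": dict(zip(site_ids, taus.tolist())),
        "weather_effect": g,
        "seasonal_log": seas,
        "trend_log": trend,
        "step_log": steps,
        "baseline_log": config.baseline_log,
        "noise_sd": config.noise_sd,
        "t0": str(config.t0_ts.date()),
        "site_meta": meta,
    }
    return conc, truth


# ---------------------------------------------------------------------------
# Areal impacts

AREA_FEATURES = (
    "dist_center_km",
    "population_density",
    "employment_density",
    "traffic_flow",
    "median_earnings",
    "business_count",
    "transport_access",
    "green_share",
)

# true impact = linear in 3 features + one interaction (sparse causal set)
CAUSAL_COEF = {
    "dist_center_km": 0.30,
    "population_density": -0.25,
    "traffic_flow": -0.40,
}
INTERACTION = ("traffic_flow", "employment_density", -0.15)


def exponential_field(
    coords: np.ndarray, sill: float, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one realization of a zero-mean GP with exponential covariance.

    C(d) = sill * exp(-d / range_km). Cholesky with a small jitter.
    """
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = sill * np.exp(-d / range_km)
    cov[np.diag_indices_from(cov)] += 1e-9
    chol = np.linalg.cholesky(cov)
    return chol @ rng.normal(size=len(coords))


@dataclass
class AreaTruth:
    """Ground truth behind one areal feature table."""

    causal_coef: dict = field(default_factory=dict)
    interaction: tuple = INTERACTION
    field_sill: float = 0.0
    field_range_km: float = 0.0
    spatial_field: np.ndarray | None = None
    linear_part: np.ndarray | None = None
    noise_sd: float = 0.0


def generate_area_impacts(
    config: SimConfig,
    field_sill: float = 0.3,
    field_range_km: float = 8.0,
    noise_sd: float = 0.15,
    causal_coef: dict | None = None,
) -> tuple[pd.DataFrame, np.ndarray, AreaTruth]:
    """Areal feature table plus the true impact vector it generates.

    Features are correlated Gaussians (urban covariates co-vary: density,
    employment and traffic rise together toward the center); the true impact
    is a sparse linear function of 3 features plus one interaction, a
    spatially correlated exponential field, and iid noise. Impacts are in
    percentage points of relative concentration change.
    """
    if config.n_areas < 30:
        raise ConfigError("n_areas must be >= 30")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n = config.n_areas
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    centroids = (
        np.c_[xs.ravel(), ys.ravel()][:n] * (config.domain_km / side)
        + config.domain_km / (2 * side)
    )
    center = np.array([config.domain_km / 2, config.domain_km / 2])
    dist_center = np.sqrt(((centroids - center) ** 2).sum(1))
    # correlated latent urbanness drives several features
    urban = -dist_center / dist_center.std() + rng.normal(0, 0.5, n)
    feats = pd.DataFrame(
        {
            "area_id": [f"area{i:03d}" for i in range(n)],
            "dist_center_km": dist_center,
            "population_density": urban + rng.normal(0, 0.6, n),
            "employment_density": 0.8 * urban + rng.normal(0, 0.7, n),
            "traffic_flow": 0.6 * urban + rng.normal(0, 0.8, n),
            "median_earnings": 0.3 * urban + rng.normal(0, 1.0, n),
            "business_count": 0.7 * urban + rng.normal(0, 0.8, n),
            "transport_access": 0.5 * urban + rng.normal(0, 0.9, n),
            "green_share": -0.4 * urban + rng.normal(0, 0.9, n),
            "x_km": centroids[:, 0],
            "y_km": centroids[:, 1],
        }
    )
    coef = CAUSAL_COEF if causal_coef is None else causal_coef
    z = {c: (feats[c] - feats[c].mean()) / feats[c].std() for c in feats.columns
         if c not in ("area_id", "x_km", "y_km")}
    linear = sum(b * z[c].to_numpy() for c, b in coef.items())
    if not isinstance(linear, np.ndarray):
        linear = np.zeros(n)
    fa, fb, fc = INTERACTION
    if coef:  # interaction only active alongside the causal set
        linear = linear + fc * z[fa].to_numpy() * z[fb].to_numpy()
    if field_sill > 0:
        spatial = exponential_field(centroids, field_sill, field_range_km, rng)
    else:
        spatial = np.zeros(n)
    noise = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    impact = -8.0 + linear + spatial + noise  # pp; negative = reduction
    truth = AreaTruth(
        causal_coef=dict(coef),
        field_sill=field_sill,
        field_range_km=field_range_km,
        spatial_field=spatial,
        linear_part=linear,
        noise_sd=noise_sd,
    )
    return feats, impact, truth


def simulate_city(config: SimConfig) -> dict:
    """Full synthetic bundle: weather, concentrations, metadata, areas, truth."""
    weather = generate_weather(config)
    conc, truth = generate_site_series(config, weather)
    areas, impact, area_truth = generate_area_impacts(config)
    return {
        "weather": weather,
        "conc": conc,
        "site_meta": truth["site_meta"],
        "truth": truth,
        "areas": areas,
        "area_impact": impact,
        "area_truth": area_truth,
    }


# ---------------------------------------------------------------------------
# Writers (long-format CSV per the package's external interface)

def write_hourly_long(frame: pd.DataFrame, variable: str, path) -> None:
    """Write a wide timestamp×site frame as long CSV (timestamp, site_id, variable, value)."""
    long = frame.reset_index(names="timestamp").melt(
        id_vars="timestamp", var_name="site_id", value_name="value"
    )
    long["variable"] = variable
    long["timestamp"] = long["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    long[["timestamp", "site_id", "variable", "value"]].to_csv(path, index=False)


def read_hourly_long(path) -> pd.DataFrame:
    """Inverse of :func:`write_hourly_long` for a single-variable file."""
    long = pd.read_csv(path, parse_dates=["timestamp"])
    return long.pivot(index="timestamp", columns="site_id", values="value")
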