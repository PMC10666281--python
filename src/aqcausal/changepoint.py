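"""Structural-change detection on normalized daily concentration series.

Penalized piecewise-linear segmentation solved exactly by dynamic
programming: each segment is fit by least squares with its own intercept
and slope (so both level discontinuities and slope changes are allowed at
every breakpoint), the per-segment cost is the residual sum of squares,
and each breakpoint pays a BIC-style penalty c·σ̂²·log(n). The DP returns
the global optimum, which the test suite checks against exhaustive
enumeration of all segmentations on short series.

A site is classified as having responded to the intervention if at least
one detected change date falls inside the symmetric margin period around
T0; the detected changes outside the margin also bound the research window
handed to the regression-discontinuity stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default multiplier c of the sigma^2·log(n) per-breakpoint penalty.
#: A breakpoint adds ~3 parameters (level, slope, position); c = 3 is the
#: BIC count, one sigma^2·log(n) per parameter.
DEFAULT_PENALTY_C = 3.0


@dataclass
class MarginPeriod:
    """Symmetric window around T0 used for response classification and as
    the donut hole of the RDD. ``half_width_days`` >= 1."""

    half_width_days: int = 7

    def __post_init__(self) -> None:
        if self.half_width_days < 1:
            raise ValueError("margin half-width must be >= 1 day")

    def window(self, t0: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        hw = pd.Timedelta(days=self.half_width_days)
        return t0 - hw, t0 + hw

    def contains(self, date: pd.Timestamp, t0: pd.Timestamp) -> bool:
        lo, hi = self.window(t0)
        return lo <= date <= hi  # closed interval


@dataclass
class ChangePointSet:
    """Detected changes for one series: ordered dates, per-change type
    (level/slope), the fitted piecewise-linear values, and the penalty used."""

    dates: list  # pd.Timestamp, strictly increasing, strictly inside series
    types: list  # "level" | "slope"
    fitted: pd.Series
    penalty: float
    breakpoints: list  # integer positions (start index of each new segment)


def _segment_cost_matrix(y: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of the least-squares line on y[i:j] (j exclusive).

    O(n^2) via prefix sums; entries for segments of length < 2 are 0.
    """
    n = len(y)
    x = np.arange(n, dtype=float)
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    i = np.arange(n)[:, None]
    j = np.arange(n + 1)[None, :]
    m = (c1[j] - c1[i]).clip(min=1)
    sx = cx[j] - cx[i]
    sy = cy[j] - cy[i]
    sxx = cxx[j] - cxx[i]
    syy = cyy[j] - cyy[i]
    sxy = cxy[j] - cxy[i]
    vx = sxx - sx * sx / m
    vy = syy - sy * sy / m
    vxy = sxy - sx * sy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = vy - np.where(vx > 1e-12, vxy * vxy / np.where(vx > 0, vx, 1.0), 0.0)
    return np.clip(sse, 0.0, None)


def _fit_line(y: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Intercept/slope of the LS line on y[i:j] in global x coordinates."""
    x = np.arange(i, j, dtype=float)
    if j - i == 1:
        return float(y[i]), 0.0
    b, a = np.polyfit(x, y[i:j], 1)
    return float(a), float(b)


def noise_scale(y: np.ndarray) -> float:
    """Robust daily noise sd from first differences (MAD-based), immune to
    trends and isolated jumps."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def detect_change_points(
    daily: pd.DataFrame | pd.Series,
    penalty: float | None = None,
    min_seg_len: int = 14,
    penalty_c: float | None = None,
    level_tol: float | None = None,
) -> ChangePointSet:
    """Globally optimal penalized piecewise-linear segmentation.

    Parameters
    ----------
    daily : output of ``daily_average`` (frame with a ``value`` column) or a
        plain Series indexed by date.
    penalty : per-breakpoint penalty; default ``penalty_c * sigma^2 * log(n)``
        with sigma estimated robustly from first differences.
    min_seg_len : minimum days per segment (prevents micro-segments).
    level_tol : absolute jump in fitted value above which a breakpoint is
        labelled ``level`` rather than ``slope``; default ``3 * sigma /
        sqrt(min_seg_len)`` (≈ the standard error of a fitted endpoint).
    """
    values = daily["value"] if isinstance(daily, pd.DataFrame) else daily
    y = values.to_numpy(dtype=float)
    index = values.index
    n = len(y)
    if n < 2 * min_seg_len:
        raise ValueError(f"series has {n} days; need >= {2 * min_seg_len}")
    sigma = noise_scale(y)
    if penalty is None:
        if penalty_c is None:
            penalty_c = DEFAULT_PENALTY_C
        # floor sigma at a fraction of the data range so noise-free series
        # keep a strictly positive penalty above numerical SSE jitter
        sigma_eff = max(sigma, 1e-3 * max(float(np.ptp(y)), 1.0))
        penalty = penalty_c * sigma_eff**2 * np.log(n)
    cost = _segment_cost_matrix(y)
    # DP over segment ends; best[j] = optimal cost of y[:j]
    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -penalty  # first segment pays no breakpoint penalty
    for j in range(min_seg_len, n + 1):
        starts = np.arange(0, j - min_seg_len + 1)
        cand = best[starts] + cost[starts, j] + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = starts[k]
    # backtrack
    bps = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            bps.append(int(i))
        j = i
    bps = sorted(bps)
    # fitted piecewise values and post-hoc type labels
    bounds = [0] + bps + [n]
    fitted = np.empty(n)
    lines = []
    for i, jj in zip(bounds[:-1], bounds[1:]):
        a, b = _fit_line(y, i, jj)
        lines.append((a, b))
        fitted[i:jj] = a + b * np.arange(i, jj)
    if level_tol is None:
        level_tol = 3.0 * sigma / np.sqrt(min_seg_len)
    types = []
    for k, bp in enumerate(bps):
        a_l, b_l = lines[k]
        a_r, b_r = lines[k + 1]
        jump = (a_r + b_r * bp) - (a_l + b_l * bp)
        types.append("level" if abs(jump) > level_tol else "slope")
    return ChangePointSet(
        dates=[index[bp] for bp in bps],
        types=types,
        fitted=pd.Series(fitted, index=index, name="fitted"),
        penalty=float(penalty),
        breakpoints=bps,
    )


def classify_response(
    cps: ChangePointSet, mp: MarginPeriod, t0: pd.Timestamp
) -> bool:
    """True iff at least one change date lies in [T0 - hw, T0 + hw]."""
    t0 = pd.Timestamp(t0)
    return any(mp.contains(pd.Timestamp(d), t0) for d in cps.dates)


def select_research_period(
    cps: ChangePointSet,
    mp: MarginPeriod,
    t0: pd.Timestamp,
    daily: pd.DataFrame | pd.Series,
    min_side_days: int = 30,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Date window for the RDD: between the nearest change points outside
    the margin period, exclusive of those change dates, clipped to the
    series extent. Change points inside the margin never clip.
    """
    values = daily["value"] if isinstance(daily, pd.DataFrame) else daily
    t0 = pd.Timestamp(t0)
    lo_mp, hi_mp = mp.window(t0)
    start = values.index[0]
    end = values.index[-1]
    day = pd.Timedelta(days=1)
    for d in cps.dates:
        d = pd.Timestamp(d)
        if d < lo_mp and d + day > start:
            start = d + day
        if d > hi_mp and d - day < end:
            end = d - day
    if not (start <= t0 <= end):
        raise ValueError("research window does not contain T0")
    if (t0 - start) < pd.Timedelta(days=min_side_days) or (end - t0) < pd.Timedelta(
        days=min_side_days
    ):
        raise ValueError(
            f"research window side shorter than {min_side_days} days; "
            "consider increasing the CPD penalty"
        )
    return start, end
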