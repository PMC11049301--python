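"""Storage-stability assessment and shelf-life prediction.

The degradation model is a straight line in storage time fitted by
ordinary least squares to the individual vial measurements.  Stability
at a checkpoint day is adjudicated by a cumulative-window slope test:
all checkpoint measurements up to and including that day enter the fit,
and the material is *acceptable* when ``t_cal = |b1|/se(b1)`` stays
below the two-sided Student-t critical value at ``n - 2`` degrees of
freedom.  Because the window grows with each checkpoint, the critical
value shrinks as the study accumulates evidence.

Shelf life is read off the 95% prediction band for a single new
measurement: the predicted usable life ends at the first day where the
band leaves the acceptance limits.  The instability contribution to the
combined uncertainty budget over a storage horizon ``T`` is
``u_sta = se(b1) * T``.

By default day 0 is excluded from the cumulative windows (the baseline
anchors the acceptance limits, not the trend test); pass
``include_baseline=True`` to keep it.  A per-day Welch comparison
against the day-0 measurements is available as an alternative mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import StabilitySeries

__all__ = [
    "TrendFit", "CheckpointTest", "ShelfLifeEstimate", "StabilityTrend",
    "StabilityResults", "fit_trend", "checkpoint_test",
    "baseline_comparison_test", "stability_uncertainty",
    "prediction_band_point", "estimate_shelf_life",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS line of concentration on storage day."""

    b0: float        # intercept, mg/dL
    b1: float        # slope, mg/dL per day
    se_b1: float     # standard error of the slope
    s_res: float     # residual SD, mg/dL
    n: int
    df: int          # n - 2
    mean_day: float
    sxx_day: float   # centred sum of squares of the day covariate


@dataclass(frozen=True)
class CheckpointTest:
    day: float
    t_cal: float
    t_critical: float
    df: int
    acceptable: bool

    def summary_row(self) -> dict:
        return {"day": self.day, "t_cal": round(self.t_cal, 2),
                "t_critical": round(self.t_critical, 2),
                "interpretation":
                    "Acceptable" if self.acceptable else "Unacceptable"}


@dataclass(frozen=True)
class ShelfLifeEstimate:
    crossing_day_lower: float | None
    crossing_day_upper: float | None
    limit_lower: float
    limit_upper: float
    level: float
    u_sta_at: Callable[[float], float]

    @property
    def shelf_life_days(self) -> float | None:
        """First band-limit crossing, whichever side comes first."""
        days = [d for d in (self.crossing_day_lower, self.crossing_day_upper)
                if d is not None]
        return min(days) if days else None


def _window_days(series: StabilitySeries, through_day: float,
                 checkpoint_days: Sequence[float] | None,
                 include_baseline: bool) -> list[float]:
    if checkpoint_days is None:
        checkpoint_days = series.days
    return [float(d) for d in checkpoint_days
            if (d > 0 or include_baseline) and d <= through_day]


def fit_trend(series: StabilitySeries, through_day: float,
              checkpoint_days: Sequence[float] | None = None,
              include_baseline: bool = False) -> TrendFit:
    """Fit the linear trend over the cumulative checkpoint window.

    The fit runs on individual vial measurements, not day means, so the
    residual SD reflects measurement scatter and the prediction band is
    a band for a single future measurement.
    """
    days = _window_days(series, through_day, checkpoint_days,
                        include_baseline)
    t, y = series.window(days)
    if len(np.unique(t)) < 2:
        raise ValueError("trend window has a single distinct day")
    if len(t) < 3:
        raise ValueError("trend fit needs at least 3 measurements")
    mean_t = t.mean()
    sxx = float(((t - mean_t) ** 2).sum())
    b1 = float(((t - mean_t) * (y - y.mean())).sum() / sxx)
    b0 = float(y.mean() - b1 * mean_t)
    resid = y - (b0 + b1 * t)
    df = len(t) - 2
    s_res = math.sqrt(float((resid ** 2).sum()) / df)
    se_b1 = s_res / math.sqrt(sxx)
    return TrendFit(b0=b0, b1=b1, se_b1=se_b1, s_res=s_res,
                    n=len(t), df=df, mean_day=float(mean_t), sxx_day=sxx)


def checkpoint_test(series: StabilitySeries, day: float,
                    alpha: float = 0.05,
                    checkpoint_days: Sequence[float] | None = None,
                    include_baseline: bool = False) -> CheckpointTest:
    """Slope significance test on the cumulative window through ``day``."""
    fit = fit_trend(series, day, checkpoint_days, include_baseline)
    if fit.df < 1:
        raise ValueError("checkpoint test needs df >= 1")
    t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df))
    if fit.se_b1 == 0.0:
        # perfect line: zero slope is stable, nonzero slope is certain drift
        t_cal = 0.0 if fit.b1 == 0.0 else math.inf
    else:
        t_cal = abs(fit.b1) / fit.se_b1
    return CheckpointTest(day=float(day), t_cal=float(t_cal),
                          t_critical=t_crit, df=fit.df,
                          acceptable=t_cal < t_crit)


def baseline_comparison_test(series: StabilitySeries, day: float,
                             alpha: float = 0.05) -> CheckpointTest:
    """Alternative mode: Welch two-sample t of day-``day`` values vs day 0."""
    t0, y0 = series.window([0.0])
    td, yd = series.window([float(day)])
    if len(y0) < 2 or len(yd) < 2:
        raise ValueError("baseline comparison needs >= 2 values per day")
    res = stats.ttest_ind(yd, y0, equal_var=False)
    df = float(res.df)
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    t_cal = abs(float(res.statistic))
    return CheckpointTest(day=float(day), t_cal=t_cal, t_critical=t_crit,
                          df=int(round(df)), acceptable=t_cal < t_crit)


def stability_uncertainty(fit: TrendFit, horizon_days: float) -> float:
    """Instability standard uncertainty over a storage horizon."""
    if horizon_days < 0:
        raise ValueError("horizon must be nonnegative")
    if fit.df < 1:
        raise ValueError("fit has no residual degrees of freedom")
    return fit.se_b1 * horizon_days


def prediction_band_point(fit: TrendFit, day: float,
                          level: float = 0.95) -> tuple[float, float]:
    """Prediction interval for a single new measurement at ``day``."""
    if fit.df < 1:
        raise ValueError("prediction band needs df >= 1")
    centre = fit.b0 + fit.b1 * day
    if fit.s_res == 0.0:
        return centre, centre  # degenerate band: collapses to the line
    t_q = stats.t.ppf((1 + level) / 2, fit.df)
    half = t_q * fit.s_res * math.sqrt(
        1 + 1 / fit.n + (day - fit.mean_day) ** 2 / fit.sxx_day)
    return centre - half, centre + half


def _first_crossing(f: Callable[[float], float], horizon: float,
                    step: float = 0.1, tol: float = 0.01) -> float | None:
    """Smallest t in (0, horizon] with f(t) >= 0, given f(0+) < 0."""
    grid = np.arange(step, horizon + step, step)
    grid = grid[grid <= horizon]
    vals = np.array([f(t) for t in grid])
    hits = np.nonzero(vals >= 0)[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    lo = grid[i] - step if i > 0 else np.finfo(float).tiny
    if f(lo) >= 0:
        return float(grid[i]) if i > 0 else float(grid[0])
    return float(optimize.brentq(f, lo, grid[i], xtol=tol))


def estimate_shelf_life(fit: TrendFit, limit_lower: float,
                        limit_upper: float, level: float = 0.95,
                        horizon: float = 1095.0) -> ShelfLifeEstimate:
    """Days until the prediction band first leaves the acceptance limits.

    Crossings are located by grid scan plus bisection to 0.1-day
    resolution, separately for the lower band against ``limit_lower``
    and the upper band against ``limit_upper``.
    """
    if not (limit_lower < fit.b0 < limit_upper):
        raise ValueError("acceptance limits must bracket the day-0 fit")

    def lower_gap(t: float) -> float:
        return limit_lower - prediction_band_point(fit, t, level)[0]

    def upper_gap(t: float) -> float:
        return prediction_band_point(fit, t, level)[1] - limit_upper

    cross_lo = (None if lower_gap(0.0) >= 0 else
                _first_crossing(lower_gap, horizon))
    cross_hi = (None if upper_gap(0.0) >= 0 else
                _first_crossing(upper_gap, horizon))
    return ShelfLifeEstimate(
        crossing_day_lower=cross_lo, crossing_day_upper=cross_hi,
        limit_lower=limit_lower, limit_upper=limit_upper, level=level,
        u_sta_at=lambda t: stability_uncertainty(fit, t))


@dataclass(frozen=True)
class StabilityResults:
    """Fitted stability assessment for one material."""

    material_id: str
    checkpoints: tuple[CheckpointTest, ...]
    final_fit: TrendFit
    shelf_life: ShelfLifeEstimate | None

    @property
    def all_acceptable(self) -> bool:
        return all(c.acceptable for c in self.checkpoints)

    def u_sta(self, horizon_days: float) -> float:
        return stability_uncertainty(self.final_fit, horizon_days)

    def summary(self):
        import pandas as pd
        return pd.DataFrame([c.summary_row() for c in self.checkpoints])

    def to_dict(self) -> dict:
        sl = self.shelf_life
        return {
            "material_id": self.material_id,
            "checkpoints": [c.summary_row() | {"df": c.df}
                            for c in self.checkpoints],
            "slope_mg_dl_per_day": self.final_fit.b1,
            "slope_se": self.final_fit.se_b1,
            "all_acceptable": self.all_acceptable,
            "shelf_life_days":
                None if sl is None else sl.shelf_life_days,
        }


class StabilityTrend:
    """Stability model over a measurement series.

    Parameters
    ----------
    series : StabilitySeries
        (day, vial, value) records.
    checkpoint_days : sequence of float, optional
        Days that participate in the cumulative windows; defaults to the
        distinct days present in the series.
    test_days : sequence of float, optional
        Days at which a checkpoint verdict is issued; defaults to every
        checkpoint day from the second onward (the first window with two
        distinct days).
    alpha, level : float
        Test level for checkpoints; coverage level for the band.
    limits : (lower, upper) in mg/dL, optional
        Acceptance limits for shelf-life prediction.  No default: limits
        are a product decision, not a statistical one.
    limits_pct : float, optional
        Convenience: limits at +/- this percent of the day-0 fitted value.
    include_baseline : bool
        Keep day-0 records inside the cumulative trend windows.
    """

    def __init__(self, series: StabilitySeries,
                 checkpoint_days: Sequence[float] | None = None,
                 test_days: Sequence[float] | None = None,
                 alpha: float = 0.05, level: float = 0.95,
                 limits: tuple[float, float] | None = None,
                 limits_pct: float | None = None,
                 include_baseline: bool = False,
                 horizon: float = 1095.0):
        self.series = series
        nonzero = [d for d in (checkpoint_days or series.days) if d > 0
                   or include_baseline]
        self.checkpoint_days = tuple(sorted(float(d) for d in nonzero))
        if test_days is None:
            test_days = self.checkpoint_days[1:]
        self.test_days = tuple(sorted(float(d) for d in test_days))
        self.alpha = alpha
        self.level = level
        self.limits = limits
        self.limits_pct = limits_pct
        self.include_baseline = include_baseline
        self.horizon = horizon

    @classmethod
    def from_dataframe(cls, df, material_id: str | None = None, **kw):
        return cls(StabilitySeries.from_frame(df, material_id), **kw)

    def fit(self) -> StabilityResults:
        checks = tuple(
            checkpoint_test(self.series, d, self.alpha,
                            self.checkpoint_days, self.include_baseline)
            for d in self.test_days)
        final = fit_trend(self.series, self.test_days[-1],
                          self.checkpoint_days, self.include_baseline)
        shelf = None
        limits = self.limits
        if limits is None and self.limits_pct is not None:
            limits = (final.b0 * (1 - self.limits_pct / 100),
                      final.b0 * (1 + self.limits_pct / 100))
        if limits is not None and final.s_res > 0:
            shelf = estimate_shelf_life(final, limits[0], limits[1],
                                        self.level, self.horizon)
        return StabilityResults(material_id=self.series.material_id,
                                checkpoints=checks, final_fit=final,
                                shelf_life=shelf)
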