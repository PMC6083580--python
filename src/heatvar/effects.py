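"""Effect surfaces extracted from the fitted model.

Two summaries drive the downstream analyses:

* the daily fixed-interval series — the log relative risk of death for a
  2 degC increase above the study-period 90th percentile of the lagged
  exposure, evaluated at every warm-season day's time index (the input to
  the change-point analysis);
* the per-summer overall effect — the percent change in mortality from the
  city-specific threshold Tref (the turning point above which mortality
  starts to increase) to that summer's maximum observed exposure.

Percent changes are (e^beta - 1) * 100 for a log-RR beta; 95% confidence
intervals use +/- 1.96 SE on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FittedModel, tensor_contrast

logger = logging.getLogger("heatvar")

__all__ = [
    "SummerEffect",
    "fixed_interval_series",
    "annual_fixed_effect",
    "estimate_tref",
    "summer_effect",
    "annual_effects_table",
    "FIXED_INTERVAL_C",
    "Z95",
]

FIXED_INTERVAL_C = 2.0        # degC increment above the 90th percentile
Z95 = 1.959963984540054       # normal 97.5% quantile
MIDSEASON_DOS = 92            # day-of-season used for annual summaries
MIN_STABLE_DAYS = 5           # fewer exceedance days -> "unstable" flag


@dataclass
class SummerEffect:
    """Overall effect of one summer: Tref to that year's maximum exposure."""

    year: int
    percent_change: float
    ci_low: float
    ci_high: float
    logrr: float
    se: float
    n_days_above_tref: int
    unstable: bool
    defined: bool = True


def _pct(logrr: np.ndarray) -> np.ndarray:
    return (np.exp(logrr) - 1.0) * 100.0


def fixed_interval_series(model: FittedModel, frame: pd.DataFrame,
                          interval: float = FIXED_INTERVAL_C) -> pd.DataFrame:
    """Daily log-RR series for a +``interval`` degC step above the 90th percentile.

    t0 is the study-period p90 of the lagged exposure, t1 = t0 + interval
    (clamped to the observed maximum with a warning if it falls beyond),
    evaluated at each warm-season day's time index.  One row per frame row:
    date, time, year, logrr, se, pct_change, ci_low, ci_high.
    """
    t0 = model.percentiles["p90"]
    t1 = t0 + interval
    if t1 > model.percentiles["max"]:
        logger.warning("p90 + %.1f degC exceeds the fitted maximum %.2f; clamping",
                       interval, model.percentiles["max"])
        t1 = model.percentiles["max"]
    times = frame["time"].to_numpy(dtype=float)
    logrr, se = tensor_contrast(model, t1, t0, times)
    out = pd.DataFrame({
        "date": frame["date"].to_numpy(),
        "time": frame["time"].to_numpy(),
        "year": frame["year"].to_numpy(),
        "logrr": logrr,
        "se": se,
    })
    out["pct_change"] = _pct(logrr)
    out["ci_low"] = _pct(logrr - Z95 * se)
    out["ci_high"] = _pct(logrr + Z95 * se)
    return out


def _midseason_time(frame: pd.DataFrame, year: int) -> float:
    g = frame[frame["year"] == year]
    if len(g) == 0:
        raise ValueError(f"year {year} not in the study period")
    idx = (g["dos"] - MIDSEASON_DOS).abs().idxmin()
    return float(g.loc[idx, "time"])


def annual_fixed_effect(model: FittedModel, frame: pd.DataFrame, year: int,
                        interval: float = FIXED_INTERVAL_C,
                        mode: str = "midseason") -> dict:
    """Per-summer fixed-interval effect.

    ``mode='midseason'`` (default) evaluates the daily contrast at the
    year's mid-season day (day of season 92); ``mode='mean'`` averages the
    daily log-RRs over the season instead — a sensitivity alternative since
    either collapse of the within-year series is defensible.
    """
    if mode not in ("midseason", "mean"):
        raise ValueError("mode must be 'midseason' or 'mean'")
    t0 = model.percentiles["p90"]
    t1 = min(t0 + interval, model.percentiles["max"])
    if mode == "midseason":
        tm = _midseason_time(frame, year)
        logrr, se = tensor_contrast(model, t1, t0, tm)
        b, s = float(logrr[0]), float(se[0])
    else:
        g = frame[frame["year"] == year]
        if len(g) == 0:
            raise ValueError(f"year {year} not in the study period")
        logrr, se = tensor_contrast(model, t1, t0, g["time"].to_numpy(dtype=float))
        b = float(logrr.mean())
        s = float(np.sqrt(np.mean(se ** 2)))  # conservative; ignores covariance
    return {
        "year": int(year),
        "logrr": b,
        "se": s,
        "pct_change": float(_pct(np.array(b))),
        "ci_low": float(_pct(np.array(b - Z95 * s))),
        "ci_high": float(_pct(np.array(b + Z95 * s))),
    }


def _averaged_curve(model: FittedModel, grid: np.ndarray) -> np.ndarray:
    """Fitted tensor prediction per grid temperature, averaged over every
    observed warm-season time index (Tref is held constant over time)."""
    a, b = model.layout["tensor"]
    theta = model.params[a:b]
    # The curve is smooth in time, so a stride over times loses nothing.
    times = model.times
    if len(times) > 400:
        times = times[:: max(1, len(times) // 400)]
    curve = np.empty(len(grid))
    for i, t in enumerate(grid):
        rows = model.tensor_row(np.full(len(times), t), times)
        curve[i] = float(np.mean(rows @ theta))
    return curve


def estimate_tref(model: FittedModel, grid_step: float = 0.1,
                  override: float | None = None,
                  method: str = "segmented") -> float:
    """Turning-point temperature above which mortality starts to increase.

    The time-averaged fitted curve is evaluated on a temperature grid and a
    turning point is sought over [p25, p95] (the range excludes spline edge
    artifacts).  ``method='segmented'`` (default) fits a flat-then-linear
    hockey stick to the curve, weighted by the square-root density of the
    observed exposures, and returns the break point — the point where the
    curve starts to increase.  ``method='argmin'`` returns the grid point
    minimizing the averaged curve; because a low-dimensional spline dips
    below zero just before a sharp rise, the argmin sits systematically
    below the true turning point, so it is kept only as a sensitivity
    alternative.  A configured ``override`` short-circuits the estimator;
    a curve that never rises (fitted heat slope <= 0) returns the lower
    boundary with a warning.
    """
    if override is not None:
        return float(override)
    if method not in ("segmented", "argmin"):
        raise ValueError("method must be 'segmented' or 'argmin'")
    lo, hi = model.percentiles["p25"], model.percentiles["p95"]
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    if method == "argmin":
        curve = _averaged_curve(model, grid)
        k = int(np.argmin(curve))
        if k == 0:
            logger.warning("averaged fitted curve is increasing over the "
                           "search range; Tref set to the lower boundary %.2f",
                           grid[0])
        return float(grid[k])

    # Segmented fit over the full observed range, break point over [p25, p95].
    eval_grid = np.arange(model.percentiles["min"], model.percentiles["max"],
                          grid_step)
    curve = _averaged_curve(model, eval_grid)
    hist, _ = np.histogram(model.exposures,
                           bins=np.append(eval_grid, eval_grid[-1] + grid_step))
    w = np.sqrt(hist.astype(float) + 1.0)

    best_sse, best_k, best_slope = np.inf, float(grid[0]), 0.0
    cw = curve * w
    for k in grid:
        x = np.column_stack([np.ones(len(eval_grid)),
                             np.maximum(0.0, eval_grid - k)])
        xw = x * w[:, None]
        coef, *_ = np.linalg.lstsq(xw, cw, rcond=None)
        r = cw - xw @ coef
        sse = float(r @ r)
        if sse < best_sse:
            best_sse, best_k, best_slope = sse, float(k), float(coef[1])
    if best_slope <= 0:
        logger.warning("no rising segment found in the averaged fitted curve; "
                       "Tref set to the lower boundary %.2f", grid[0])
        return float(grid[0])
    return best_k


def summer_effect(model: FittedModel, frame: pd.DataFrame, year: int,
                  tref: float, min_days: int = MIN_STABLE_DAYS) -> SummerEffect:
    """Percent change from Tref to the year's maximum observed exposure.

    Evaluated at the year's mid-season time index.  Years with no day above
    Tref yield a flagged null result rather than an exception; years with
    fewer than ``min_days`` exceedance days are flagged unstable (their
    intervals are wide).
    """
    g = frame[frame["year"] == year]
    if len(g) == 0:
        raise ValueError(f"year {year} not in the study period")
    tmax = float(g["tmean_n"].max())
    n_above = int((g["tmean_n"] > tref).sum())
    if n_above == 0:
        return SummerEffect(year=int(year), percent_change=float("nan"),
                            ci_low=float("nan"), ci_high=float("nan"),
                            logrr=float("nan"), se=float("nan"),
                            n_days_above_tref=0, unstable=True, defined=False)
    tm = _midseason_time(frame, year)
    logrr, se = tensor_contrast(model, tmax, tref, tm)
    b, s = float(logrr[0]), float(se[0])
    return SummerEffect(
        year=int(year),
        percent_change=float(_pct(np.array(b))),
        ci_low=float(_pct(np.array(b - Z95 * s))),
        ci_high=float(_pct(np.array(b + Z95 * s))),
        logrr=b, se=s, n_days_above_tref=n_above,
        unstable=n_above < min_days)


def annual_effects_table(model: FittedModel, frame: pd.DataFrame, tref: float,
                         interval: float = FIXED_INTERVAL_C,
                         mode: str = "midseason") -> pd.DataFrame:
    """One row per study year: fixed-interval and summer-wide effects."""
    rows = []
    for year in sorted(frame["year"].unique()):
        fixed = annual_fixed_effect(model, frame, year, interval, mode)
        summer = summer_effect(model, frame, year, tref)
        rows.append({
            "year": int(year),
            "fixed_pct": fixed["pct_change"],
            "fixed_ci_low": fixed["ci_low"],
            "fixed_ci_high": fixed["ci_high"],
            "summer_pct": summer.percent_change,
            "summer_ci_low": summer.ci_low,
            "summer_ci_high": summer.ci_high,
            "n_days_above_tref": summer.n_days_above_tref,
            "unstable": summer.unstable,
        })
    return pd.DataFrame(rows)
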