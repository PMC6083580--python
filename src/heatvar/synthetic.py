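"""Synthetic daily city series with known heat-mortality ground truth.

Generates full-calendar-year daily records of mean air temperature and
all-natural-cause death counts with the statistical structure the warm-season
analysis assumes: a seasonal temperature cycle with AR(1) weather noise,
warming trend and heat-wave episodes; and Poisson (optionally overdispersed)
deaths with seasonal, day-of-week, holiday and previous-winter-mortality
structure plus a hockey-stick heat effect above a threshold whose log-linear
slope may change over the years (step change or drift).

Because every generative parameter is recorded, the per-year true effect
sizes (percent mortality change for a +2 °C increment, heat-attributable
deaths) are available in closed form, which is what makes downstream
parameter-recovery testing possible without any real city data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClimateConfig",
    "MortalityTruth",
    "SimulationTruth",
    "DEFAULT_HOLIDAYS",
    "simulate_temperature",
    "simulate_mortality",
    "make_city",
    "write_city_csv",
    "write_truth_yaml",
]

# Fixed-date public holidays (month, day); country-agnostic, deterministic.
DEFAULT_HOLIDAYS: tuple[tuple[int, int], ...] = ((1, 1), (5, 1), (8, 15), (12, 25))

# Day-of-year phase of the annual temperature cycle: trough at mid-January
# (doy 15), peak about six months later (mid-July).
_PHASE_DOY = 15.0
_YEAR_DAYS = 365.25


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class ClimateConfig:
    """Parameters of the daily temperature generator.

    Units are °C throughout; ``warming_trend`` is °C per year and
    ``heatwave_rate`` is the expected number of episodes per warm season.
    """

    n_years: int = 20
    start_year: int = 1991
    mean_temp: float = 16.0
    seasonal_amplitude: float = 9.0
    warming_trend: float = 0.05
    ar1_rho: float = 0.7
    ar1_sd: float = 1.8
    heatwave_rate: float = 6.0
    heatwave_mean_length: float = 5.0
    heatwave_amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        for name in ("mean_temp", "seasonal_amplitude", "warming_trend",
                     "ar1_rho", "ar1_sd", "heatwave_rate",
                     "heatwave_mean_length", "heatwave_amplitude"):
            _check_finite(name, float(getattr(self, name)))
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        for name in ("seasonal_amplitude", "ar1_sd", "heatwave_rate",
                     "heatwave_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.heatwave_mean_length < 1:
            raise ValueError("heatwave_mean_length must be >= 1 day")


@dataclass
class MortalityTruth:
    """Generative parameters of the daily death-count process.

    ``slope_by_year`` is the log relative-risk per °C of lagged exposure
    above ``tref_true`` for each study year; a step change or drift in this
    vector is the signal the tensor-smooth analysis must recover.
    ``dispersion`` is the variance/mean ratio of the counts (1 = Poisson).
    """

    baseline_deaths: float = 150.0
    seasonal_log_amplitude: float = 0.12
    dow_log_effects: Sequence[float] = (0.0, -0.01, -0.01, 0.0, 0.01, 0.02, 0.02)
    holiday_log_effect: float = 0.05
    wdd_log_slope: float = -0.002
    tref_true: float = 23.0
    slope_by_year: Sequence[float] = ()
    changepoint_year: int | None = None
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_deaths <= 0:
            raise ValueError("baseline_deaths must be > 0")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        if len(self.dow_log_effects) != 7:
            raise ValueError("dow_log_effects must have 7 entries (Mon..Sun)")

    @classmethod
    def with_step(cls, n_years: int, slope_before: float, slope_after: float,
                  changepoint_year: int, **kwargs) -> "MortalityTruth":
        """Truth whose heat slope steps at the start of ``changepoint_year``
        (0-based year index: years < changepoint_year get ``slope_before``)."""
        slopes = [slope_before] * changepoint_year + \
                 [slope_after] * (n_years - changepoint_year)
        return cls(slope_by_year=slopes, changepoint_year=changepoint_year,
                   **kwargs)

    @classmethod
    def constant_slope(cls, n_years: int, slope: float, **kwargs) -> "MortalityTruth":
        return cls(slope_by_year=[slope] * n_years, **kwargs)


@dataclass
class SimulationTruth:
    """Closed-form ground truth recorded alongside a simulated city."""

    mortality: MortalityTruth
    lag_n: int
    percent_change_2c: list[float] = field(default_factory=list)
    attributable_deaths: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mortality"]["dow_log_effects"] = list(self.mortality.dow_log_effects)
        d["mortality"]["slope_by_year"] = list(self.mortality.slope_by_year)
        return d


def _seasonal_cycle(doy: np.ndarray, amplitude: float) -> np.ndarray:
    """Annual sinusoid with trough at mid-January, peak mid-July."""
    return -amplitude * np.cos(2.0 * np.pi * (doy - _PHASE_DOY) / _YEAR_DAYS)


def _dates(config: ClimateConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{config.start_year}-01-01",
                         f"{config.start_year + config.n_years - 1}-12-31",
                         freq="D")


def simulate_temperature(config: ClimateConfig, seed: int) -> pd.Series:
    """Daily mean air temperature (°C) over ``config.n_years`` calendar years.

    The series is mean + annual sinusoid + linear warming trend + stationary
    AR(1) noise + additive heat-wave bumps.  Episode counts per warm season
    are Poisson(``heatwave_rate``), lengths geometric with the configured
    mean, placement uniform over June-August; every day of an episode is
    raised by ``heatwave_amplitude``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dates = _dates(config)
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    t = np.arange(n, dtype=float)

    temps = (config.mean_temp
             + _seasonal_cycle(doy, config.seasonal_amplitude)
             + config.warming_trend * t / _YEAR_DAYS)

    # Stationary AR(1) innovation noise.
    if config.ar1_sd > 0:
        eps = rng.normal(0.0, config.ar1_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.ar1_sd / math.sqrt(1.0 - config.ar1_rho ** 2))
        rho = config.ar1_rho
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + eps[i]
        temps = temps + noise

    # Heat-wave episodes, uniform over June-August of each year.
    if config.heatwave_rate > 0 and config.heatwave_amplitude > 0:
        years = dates.year.to_numpy()
        months = dates.month.to_numpy()
        for yr in range(config.start_year, config.start_year + config.n_years):
            candidates = np.flatnonzero((years == yr) & (months >= 6) & (months <= 8))
            n_ep = rng.poisson(config.heatwave_rate)
            for _ in range(n_ep):
                start = rng.choice(candidates)
                length = rng.geometric(1.0 / config.heatwave_mean_length)
                stop = min(start + length, n)
                temps[start:stop] += config.heatwave_amplitude

    return pd.Series(temps, index=dates, name="tmean")


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Lag 0..n moving average; the first n elements are NaN."""
    if n == 0:
        return x.astype(float)
    s = pd.Series(x)
    return s.rolling(window=n + 1).mean().to_numpy()


def _log_rate_base(dates: pd.DatetimeIndex, truth: MortalityTruth,
                   holidays: Sequence[tuple[int, int]] = DEFAULT_HOLIDAYS) -> np.ndarray:
    """Log expected deaths from baseline + seasonality + dow + holidays
    (everything except the wdd and heat terms)."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    # Mortality peaks in winter: +amplitude at mid-January.
    seasonal = truth.seasonal_log_amplitude * np.cos(
        2.0 * np.pi * (doy - _PHASE_DOY) / _YEAR_DAYS)
    dow = np.asarray(truth.dow_log_effects, dtype=float)[dates.weekday]
    hol_mask = np.zeros(len(dates), dtype=bool)
    md = list(zip(dates.month.to_numpy(), dates.day.to_numpy()))
    hol_set = set(holidays)
    hol_mask = np.array([pair in hol_set for pair in md])
    return (math.log(truth.baseline_deaths) + seasonal + dow
            + truth.holiday_log_effect * hol_mask)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Poisson draws, or negative binomial with variance = dispersion * mean."""
    if dispersion <= 1.0:
        return rng.poisson(mu)
    r = mu / (dispersion - 1.0)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _simulate_mortality_impl(temps: pd.Series, truth: MortalityTruth,
                             lag_n: int, seed: int,
                             holidays: Sequence[tuple[int, int]] = DEFAULT_HOLIDAYS,
                             ) -> tuple[pd.Series, np.ndarray]:
    """Two-pass simulation; returns (counts, expected-rate vector).

    Pass 1 draws October-March counts from the base rate; pass 2 computes
    each warm season's wdd covariate from those simulated winter counts and
    draws April-September counts with the wdd and heat terms included.
    """
    if lag_n < 0:
        raise ValueError("lag_n must be >= 0")
    dates = temps.index
    if len(np.asarray(truth.slope_by_year)) == 0:
        raise ValueError("slope_by_year is empty")
    n_years = len(truth.slope_by_year)
    start_year = int(dates[0].year)
    if int(dates[-1].year) - start_year + 1 != n_years:
        raise ValueError("temps span and slope_by_year length disagree")

    rng = np.random.default_rng(seed)
    log_base = _log_rate_base(dates, truth, holidays)
    months = dates.month.to_numpy()
    years = dates.year.to_numpy()
    winter = (months >= 10) | (months <= 3)
    summer = ~winter

    counts = np.zeros(len(dates), dtype=np.int64)
    rates = np.exp(log_base.copy())

    # Pass 1: winters (October-March) at the base rate.
    counts[winter] = _draw_counts(rng, rates[winter], truth.dispersion)

    # Long-run expected winter mean daily deaths, used to center wdd.
    winter_mean_expected = float(np.mean(rates[winter]))

    tmean_n = _moving_average(temps.to_numpy(dtype=float), lag_n)
    log_rate = log_base.copy()

    # Pass 2: warm seasons with wdd and heat terms.
    for y_idx in range(n_years):
        yr = start_year + y_idx
        season = (years == yr) & summer & (months >= 4)
        if not season.any():
            continue
        # Previous winter window Oct 1 (yr-1) .. Mar 31 (yr); use whatever
        # part lies inside the series (the first year has only Jan-Mar).
        win_mask = (((years == yr - 1) & (months >= 10))
                    | ((years == yr) & (months <= 3)))
        if win_mask.any():
            wdd = float(counts[win_mask].mean())
        else:
            wdd = winter_mean_expected
        heat = np.zeros(season.sum())
        exc = np.maximum(0.0, tmean_n[season] - truth.tref_true)
        exc = np.where(np.isnan(exc), 0.0, exc)
        heat = truth.slope_by_year[y_idx] * exc
        log_rate[season] = (log_base[season]
                            + truth.wdd_log_slope * (wdd - winter_mean_expected)
                            + heat)
        mu = np.exp(log_rate[season])
        rates[season] = mu
        counts[season] = _draw_counts(rng, mu, truth.dispersion)

    return pd.Series(counts, index=dates, name="deaths"), rates


def simulate_mortality(temps: pd.Series, truth: MortalityTruth, lag_n: int,
                       seed: int,
                       holidays: Sequence[tuple[int, int]] = DEFAULT_HOLIDAYS,
                       ) -> pd.Series:
    """Daily death counts for a given temperature series; see module docs."""
    counts, _ = _simulate_mortality_impl(temps, truth, lag_n, seed, holidays)
    return counts


def make_city(climate: ClimateConfig, truth: MortalityTruth, lag_n: int,
              seed: int,
              holidays: Sequence[tuple[int, int]] = DEFAULT_HOLIDAYS,
              ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a complete city and record its closed-form ground truth.

    One master seed spawns two independent streams (temperature, mortality)
    so that changing the climate configuration does not reshuffle the
    mortality noise.  The returned :class:`SimulationTruth` holds the exact
    per-year percent change for a +2 °C increment, (e^{2s_y}-1)*100, and the
    true expected attributable deaths per year, sum over exceedance days of
    E[y]*(1 - e^{-beta_true}).
    """
    if len(truth.slope_by_year) != climate.n_years:
        raise ValueError("slope_by_year length must equal climate.n_years")
    ss = np.random.SeedSequence(seed)
    temp_seed, mort_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    temps = simulate_temperature(climate, temp_seed)
    counts, rates = _simulate_mortality_impl(temps, truth, lag_n, mort_seed, holidays)

    dates = temps.index
    series = pd.DataFrame({
        "date": dates,
        "deaths": counts.to_numpy(),
        "tmean": temps.to_numpy(),
    })

    tmean_n = _moving_average(temps.to_numpy(dtype=float), lag_n)
    months = dates.month.to_numpy()
    years = dates.year.to_numpy()
    pct, ad = [], []
    for y_idx in range(climate.n_years):
        s = float(truth.slope_by_year[y_idx])
        pct.append((math.exp(2.0 * s) - 1.0) * 100.0)
        season = (years == climate.start_year + y_idx) & (months >= 4) & (months <= 9)
        exc = np.maximum(0.0, np.nan_to_num(tmean_n[season]) - truth.tref_true)
        beta = s * exc
        ad.append(float(np.sum(rates[season] * (1.0 - np.exp(-beta)))))

    sim_truth = SimulationTruth(mortality=truth, lag_n=lag_n,
                                percent_change_2c=pct, attributable_deaths=ad)
    return series, sim_truth


def write_city_csv(series: pd.DataFrame, path) -> None:
    """Write the schema the pipeline reads: date (ISO-8601), deaths, tmean."""
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["tmean"] = out["tmean"].map(lambda v: format(v, ".4f"))
    out.to_csv(path, index=False, lineterminator="\n")


def write_truth_yaml(truth: SimulationTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)
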