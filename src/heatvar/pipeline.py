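"""End-to-end pipeline: simulate/read -> fit -> effects -> change point -> attribution.

A single :class:`PipelineConfig` (readable from flat YAML) drives every
stage; one master seed fans out to independent per-stage streams so that
toggling one stage never perturbs another.  All percentiles, knots and Tref
are computed once at fit time, frozen into the serialized model, and reused
downstream.  Rerunning with an identical config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from . import changepoint as bcp_mod
from . import effects as eff_mod
from . import model as model_mod
from . import synthetic as syn_mod

logger = logging.getLogger("heatvar")

__all__ = ["PipelineConfig", "RunReport", "read_city_csv", "run_pipeline"]

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything tunable in one place; either an input CSV or a simulation."""

    input_csv: str | None = None
    climate: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    lag_n: int = 3
    holidays: list = field(default_factory=lambda: [list(h) for h in syn_mod.DEFAULT_HOLIDAYS])
    n_temp_interior_knots: int = 2
    dos_df: int = 6
    time_penalty: float = 0.0
    fixed_interval: float = 2.0
    annual_mode: str = "midseason"
    tref_override: float | None = None
    tref_grid_step: float = 0.1
    min_stable_days: int = 5
    truncate_negative: bool = False
    with_bcp: bool = True
    bcp: dict = field(default_factory=dict)
    seed: int = 1
    outdir: str = "heatvar_out"
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.input_csv is None and not isinstance(self.climate, dict):
            raise ValueError("provide input_csv or a simulation block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def holiday_tuples(self) -> tuple:
        return tuple(tuple(h) for h in self.holidays)


@dataclass
class RunReport:
    """Stage inventory and headline results of one pipeline run."""

    outputs: dict
    seed: int
    converged: bool
    dispersion: float
    tref: float
    detected_changepoints: list
    yearly: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunReport":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def read_city_csv(path) -> pd.DataFrame:
    """Read and validate the city schema: date, deaths, tmean.

    Dates must be contiguous daily records; deaths must be non-negative
    integers (a float like "3.0" is accepted as 3, "3.5" is rejected).
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path)
    missing = {"date", "deaths", "tmean"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable dates in {path}: {exc}") from exc

    gaps = np.flatnonzero(np.diff(dates.to_numpy()).astype("timedelta64[D]")
                          != np.timedelta64(1, "D"))
    if len(gaps):
        g = gaps[0]
        raise ValueError(
            f"date gap: missing range {dates.iloc[g].date() + pd.Timedelta(days=1)}"
            f" .. {dates.iloc[g + 1].date() - pd.Timedelta(days=1)} "
            f"(after line {g + 2})")

    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    bad = df.index[deaths.isna() | (deaths < 0) | (deaths % 1 != 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"deaths must be non-negative integers; "
                         f"offending lines: {lines}")
    out = pd.DataFrame({"date": dates, "deaths": deaths.astype(np.int64),
                        "tmean": pd.to_numeric(df["tmean"])})
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT,
              lineterminator="\n")


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0]
               % (2 ** 31))


def _truth_from_config(config: PipelineConfig, n_years: int) -> syn_mod.MortalityTruth:
    t = dict(config.truth)
    if "slope_by_year" not in t or not t["slope_by_year"]:
        t["slope_by_year"] = [0.05] * n_years
    return syn_mod.MortalityTruth(**t)


def simulate_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    climate = syn_mod.ClimateConfig(**config.climate)
    truth = _truth_from_config(config, climate.n_years)
    series, sim_truth = syn_mod.make_city(
        climate, truth, config.lag_n, _stage_seed(config.seed, 0),
        holidays=config.holiday_tuples())
    syn_mod.write_city_csv(series, outdir / "city.csv")
    syn_mod.write_truth_yaml(sim_truth, outdir / "truth.yaml")
    return series


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; every intermediate artifact is written.

    Stage failures abort with the stage name; the report lists every file
    produced and is regenerable from the outputs alone.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    level = {"quiet": logging.ERROR, "info": logging.INFO,
             "debug": logging.DEBUG}.get(config.verbosity, logging.INFO)
    logger.setLevel(level)
    outputs: dict[str, str] = {}

    stage = "input"
    try:
        if config.input_csv is not None:
            series = read_city_csv(config.input_csv)
        else:
            series = simulate_stage(config, outdir)
            outputs["city"] = str(outdir / "city.csv")
            outputs["truth"] = str(outdir / "truth.yaml")

        stage = "fit"
        frame = model_mod.build_frame(series, config.lag_n,
                                      holidays=config.holiday_tuples())
        spec = model_mod.BasisSpec.from_frame(
            frame, n_temp_interior=config.n_temp_interior_knots,
            dos_df=config.dos_df)
        fitted = model_mod.fit_model(frame, spec,
                                     time_penalty=config.time_penalty)
        fitted.save(outdir / "model.json")
        outputs["model"] = str(outdir / "model.json")

        stage = "effects"
        daily = eff_mod.fixed_interval_series(fitted, frame,
                                              interval=config.fixed_interval)
        _write_csv(daily, outdir / "daily_effects.csv")
        outputs["daily_effects"] = str(outdir / "daily_effects.csv")
        tref = eff_mod.estimate_tref(fitted, grid_step=config.tref_grid_step,
                                     override=config.tref_override)
        annual = eff_mod.annual_effects_table(
            fitted, frame, tref, interval=config.fixed_interval,
            mode=config.annual_mode)
        _write_csv(annual, outdir / "annual_effects.csv")
        outputs["annual_effects"] = str(outdir / "annual_effects.csv")

        detected_dates: list[str] = []
        if config.with_bcp:
            stage = "changepoint"
            bcp_cfg = bcp_mod.BCPConfig(seed=_stage_seed(config.seed, 2),
                                        **config.bcp)
            result = bcp_mod.run_bcp(daily["logrr"].to_numpy(), bcp_cfg)
            bcp_df = pd.DataFrame({
                "index": np.arange(len(daily)),
                "date": daily["date"],
                "posterior": result.posterior,
                "envelope": result.envelope,
                "detected": [int(i in set(result.detected))
                             for i in range(len(daily))],
            })
            _write_csv(bcp_df, outdir / "changepoints.csv")
            outputs["changepoints"] = str(outdir / "changepoints.csv")
            detected_dates = [str(pd.Timestamp(daily["date"].iloc[i]).date())
                              for i in result.detected]

        stage = "attribution"
        betas = attr_mod.daily_beta(fitted, frame, tref)
        ad = attr_mod.attributable_deaths(
            frame, betas, fitted.percentiles["p95"], tref,
            truncate_negative=config.truncate_negative)
        _write_csv(ad, outdir / "attribution.csv")
        outputs["attribution"] = str(outdir / "attribution.csv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}': {exc}; "
            f"outputs so far: {sorted(outputs)}") from exc

    yearly = annual.merge(ad, on="year", how="left")
    report = RunReport(outputs=outputs, seed=config.seed,
                       converged=fitted.converged,
                       dispersion=fitted.dispersion, tref=tref,
                       detected_changepoints=detected_dates,
                       yearly=json.loads(yearly.to_json(orient="records")))
    report.save(outdir / "report.json")
    config.to_yaml(outdir / "config_used.yaml")
    return report
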