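# heatvar

Inter-annual variability of heat-related mortality in daily city time
series: a quasi-Poisson regression with a temperature × time
tensor-product smooth, year-by-year heat-risk extraction, Bayesian
change-point detection with a simulation-calibrated significance
envelope, and mild/extreme heat-attributable death counts.

**Who it is for.** Environmental epidemiologists and public-health
analysts who have a city's daily all-natural-cause death counts and daily
mean air temperature over 15–20 years and want to know not just *whether*
heat raises mortality, but how that effect and its burden changed from
summer to summer — e.g. whether a heat-plan introduction or an extreme
year like 2003 left a detectable mark.

## The model

For warm-season days (April 1 – September 30) the daily death count
follows

```
log E(Y_i) = α + Tensor(Tmean_n, Time) + s(dos) + dow + hol + wdd
```

where `Tmean_n` is the 0..n-day moving average of mean temperature (the
exposure), `Time` the day count over the study period, `s(dos)` a 6-dof
day-of-season smooth, `dow`/`hol` day-of-week and holiday terms, and
`wdd` the previous winter's (Oct–Mar) mean daily mortality. The tensor
term is a product of cubic-regression-spline bases — temperature (two
interior knots by default) × time (one degree of freedom per study
year) — so the temperature–mortality curve varies smoothly across years.
Fitting is quasi-Poisson (Pearson-dispersion–scaled covariance).

From the fitted surface the package extracts, per summer:

* the **fixed-interval effect** — percent change in mortality,
  `(e^β − 1)·100`, for a 2 °C increase above the study-period 90th
  percentile of the exposure, daily and per year;
* the **summer-wide effect** — percent change from the threshold `Tref`
  (the turning point above which mortality starts to increase, estimated
  from the time-averaged curve) to the year's maximum exposure;
* **attributable deaths** `AD_j = Σ_i y_ij (1 − e^{−β_ijT})`, split into
  mild heat (`Tref` → overall 95th percentile) and extreme heat (above
  the 95th percentile), with `β_ijT = 0` when `T ≤ Tref`.

The daily fixed-interval log-RR series is scanned by a **Bayesian change
point** model — two Gaussian blocks with a common σ and an unknown split
`k`, Gibbs-sampled (11,000 iterations, 1,000 burn-in) — and per-day
posterior change probabilities are compared against a **null envelope**:
the smoothed 97.5% quantile of posteriors from 1,000 Gaussian series
matched to the observed mean and variance. Days above the envelope are
detected change points.

Because real multi-city mortality data are not freely redistributable,
the package ships a synthetic-city generator with full ground truth
(seasonal climate with heat waves, overdispersed counts with
day-of-week/holiday/winter-mortality structure, and a hockey-stick heat
effect whose slope can step or drift across years); every estimator is
validated against it. See `docs/methods.md` for the complete model
description and design rationale.

## Worked example

A 20-year synthetic city whose heat slope drops from 0.05 to 0.02
log-RR/°C at year 10 (true fixed-interval effects: +10.52% before,
+4.08% after):

```python
import heatvar as hv

climate = hv.ClimateConfig(n_years=20)
truth = hv.MortalityTruth.with_step(20, 0.05, 0.02, 10)
series, sim = hv.make_city(climate, truth, lag_n=3, seed=42)

frame = hv.build_frame(series, 3)
spec = hv.BasisSpec.from_frame(frame, n_temp_interior=6)
model = hv.fit_model(frame, spec, time_penalty=10.0)

tref = hv.estimate_tref(model)
for year in (1995, 2005):
    eff = hv.annual_fixed_effect(model, frame, year)
    print(f"{year}: +2C effect {eff['pct_change']:+.1f}% "
          f"[{eff['ci_low']:+.1f}, {eff['ci_high']:+.1f}]")

betas = hv.daily_beta(model, frame, tref)
ad = hv.attributable_deaths(frame, betas, model.percentiles["p95"], tref)
print("mean attributable deaths/year:", round(ad["ad_total"].mean(), 1))
```

prints

```
1995: +2C effect +7.5% [+4.1, +11.0]
2005: +2C effect +4.7% [+2.4, +7.0]
mean attributable deaths/year: 1475.8
```

The 1995 interval covers the true +10.52% and the 2005 interval the true
+4.08%; the estimated threshold (23.06 °C here) recovers the generative
23 °C, and the attributable-death total tracks the generative expectation
(1689/year) with the conservative bias discussed in the methods note.
`n_temp_interior=6` and `time_penalty=10.0` are the robust analysis
settings recommended for recovery studies; the defaults (two interior
knots, no penalty) reproduce the leaner published specification.

### Command line

The same pipeline runs as a CLI with a YAML config
(`heatvar run --config city.yaml --seed 1 --out results/`), with
subcommands `simulate`, `fit`, `effects`, `bcp`, `attribute`, `run` and
`report`. Outputs are tidy CSVs (daily effects, annual/summer effects,
change-point posterior and envelope, attributable deaths), a serialized
model, and a JSON run report; identical configs and seeds give
byte-identical outputs.

Input CSV schema: `date` (ISO-8601, contiguous daily), `deaths`
(non-negative integer), `tmean` (°C).

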