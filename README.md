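# trendpower

Residual-bootstrap power analysis for detecting temporal trends in seasonal
environmental monitoring data, built around the inshore water-quality
component of the Great Barrier Reef Marine Monitoring Program (MMP).

Long-term monitoring programs exist to detect change, yet their sampling
designs are rarely evaluated for the *power* to do so. This package answers,
for a program that switched in 2015 from 10 fixed sites visited three times a
year to 22 sites visited up to ten times a year: how much more likely is the
denser design to detect a sustained fractional change in an analyte such as
chlorophyll-a, and does the gain come from the added sites or the added
visits? It is written for monitoring-program statisticians and marine
scientists, but the machinery applies to any seasonal time series of positive
concentrations sampled at fixed stations.

## Model and method

Log-transformed analyte values are modelled by harmonic (seasonal-trend)
regression

    y_i = β₀ + β_p + β_s + β₁ x_i + β₂ cos(2π x̃_i / T) + β₃ sin(2π x̃_i / T) + ε_i

where `x_i` is elapsed days, `x̃_i` is days since January 1 of the first
sampling year (so the seasonal curve is phased relative to New Year),
`T = 365.25` days, `β_p` and `β_s` are institution and site offsets, and the
`ε_i` are uncorrelated with common variance σ². Trend inference offers
classical, Newey–West HAC, and cluster-robust (by site) covariances;
residual autocorrelation is screened with Durbin–Watson statistics under
Benjamini–Hochberg FDR control.

Power for a fractional year-on-year change δ (100δ is the percent change per
year) is estimated by residual bootstrap: fit the model, replace the fitted
trend with the target slope `s(δ) = ln(1+δ)/T` per day (exact compounding on
the log scale), resample residuals with replacement onto that expectation,
refit, and count how often the trend test rejects at α = 0.05 over R
replicates. Sweeping δ over a grid (default −0.20…0.20 by 0.01, R = 1000)
yields a power curve; the headline summary averages power at δ = ±0.1.

The companion projection inverts compounding exactly: a level *m* growing at
(1+δ) per year crosses a bound *q* after `t = ln(q/m)/ln(1+δ)` years, applied
per site against the pooled 10th/90th percentiles of the recent record.

Because the program's raw database is not public, the package ships a
synthetic-data generator that reproduces both sampling calendars (sites,
wet/dry-season visit frequencies, two institutions, surface/bottom duplicate
structure, below-detection censoring for NOx) so the entire pipeline is
testable end to end.

## Worked example

```python
import trendpower as tp

design = tp.mmp_post2015_design()["Burdekin"]
events = tp.build_design_calendar(design, seed=1)
params = tp.GeneratorParams(intercept=0.5, sigma=0.6,
                            seasonal_cos=0.25, seasonal_sin=-0.15, seed=1)
obs = tp.simulate_measurements(events, params)
table = tp.prepare_table(obs, exclusions=())
series = tp.prepare_series(table, "chl_a", "Burdekin",
                           tp.standard_windows()["post-2015"])
fit = tp.fit_ols(series)
test = tp.trend_test(fit)
print(f"n = {series.n}, R^2 = {fit.r_squared:.2f}")
print(f"trend = {fit.trend:.2e} per day (p = {test.p_value:.2f})")

config = tp.PowerConfig(delta_grid=(-0.1, 0.0, 0.1), n_boot=1000, seed=1)
curve = tp.power_curve(series, tp.ModelSpec(), config)
print(curve.table)
print(f"power at a 10%/yr change: {tp.summarize_power(curve):.3f}")
```

prints

```
n = 255, R^2 = 0.10
trend = -5.78e-05 per day (p = 0.44)
   delta  power     mc_se  n_boot
0   -0.1  0.975  0.004937    1000
1    0.0  0.050  0.006892    1000
2    0.1  0.947  0.007085    1000
power at a 10%/yr change: 0.961
```

The simulated Burdekin post-2015 design (255 depth- and replicate-averaged
visits over ~4.5 years, residual σ = 0.6) has no true trend — the fitted
slope is indistinguishable from zero — yet would detect a sustained ±10%/yr
change with probability ≈ 0.96. The δ = 0 row is the test's size and sits at
the nominal 0.05.

## Analysis workflow

The `analysis/` scripts run the study end to end on synthetic data, writing
tables under `results/`:

1. `01_simulate_monitoring_data.py` — both sampling eras, six analytes, four
   study areas;
2. `02_prepare_series.py` — averaging, exclusions, window splitting;
3. `03_fit_trend_models.py` — model fits plus the Durbin–Watson/FDR screen;
4. `04_power_design_comparison.py` — pre- vs post-2015 power per cell;
5. `05_power_scenario_decomposition.py` — sites-vs-frequency decomposition;
6. `06_time_to_exceedance.py` — years to cross the post-2015 percentiles.

The same stages are available as CLI subcommands (`trendpower simulate`,
`prepare`, `fit`, `power`, `compare-designs`, `scenarios`, `exceedance`) with
`--config/--seed/--outdir` flags, configured by a YAML file mirroring
`RunConfig`.

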