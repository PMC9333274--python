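# Methods

## The seasonal-trend model

The working model for one analyte in one study area and time window is
ordinary least squares on natural-log values:

    y_i = β₀ + β_p + β_s + β₁ x_i + β₂ cos(2π x̃_i/T) + β₃ sin(2π x̃_i/T) + ε_i

- `x_i` — days elapsed since the first retained observation in the window
  (the trend clock).
- `x̃_i` — days since January 1 of the year of that first observation (the
  seasonal clock), so the estimated seasonal curve is phased relative to
  New Year, which makes the cosine/sine pair interpretable.
- `T = 365.25` days — the average calendar year, fixed.
- `β_p`, `β_s` — institution (project) and sampling-location offsets, entered
  as indicator columns with the alphabetically first level as the omitted
  reference; the site block is dropped entirely for single-site series and
  indicator levels absent from the data are never materialised.
- `ε_i` — uncorrelated, mean zero, common variance σ².

Log transformation addresses the positive skew typical of concentration
data; the model is deliberately a fixed parametric form (no smooths, no
random effects) so that the residual bootstrap below stands on standard
regression theory and the same model applies to both sparse and dense
sampling eras. One harmonic is the default (`harmonic_order` adds further
pairs; they rarely improve fit for these analytes, and the matrix becomes
rank-deficient long before high orders are useful on sparse designs).
`include_season=False` gives the plain trend regression used by the
closed-form power oracle.

Trend inference (`trend_test`) is a two-sided t-test of β₁ = 0 under one of
three covariance estimators, all via statsmodels: classical σ̂²(XᵀX)⁻¹ with
n−p degrees of freedom; Newey–West/Bartlett HAC with the automatic lag
⌊4(n/100)^{2/9}⌋; or a cluster-robust sandwich grouped by site with the
G/(G−1)·(n−1)/(n−p) finite-cluster factor and G−1 degrees of freedom. With
every row its own cluster the cluster estimator reduces exactly to HC1 — a
sandwich identity the tests verify. Residual autocorrelation is screened
per site with the Durbin–Watson statistic; its p-value uses the large-sample
N(2, 4/n) approximation, adequate for screening many series under
Benjamini–Hochberg FDR control (and cheap compared with the exact null
distribution, which depends on the design matrix).

## The bootstrap power algorithm

Power for a fractional year-on-year change δ is estimated as:

1. Fit the model to the observed (or simulated) series; keep fitted values,
   residuals ε̂, and the design matrix X.
2. Replace the estimated trend with the target: μ*(δ) = fitted − β̂₁x + s(δ)x,
   with **s(δ) = ln(1+δ)/T per day**. Exact compounding on the log scale is
   the only mapping for which the back-transformed trend changes by exactly
   100δ% per year at every δ; it differs from the linearised δ/T by under
   0.5% of slope at |δ| ≤ 0.1. Only the trend term is substituted — the
   intercept, offsets and seasonal curve are retained, anchoring the
   injected trend at the intercept-level value at x = 0.
3. For r = 1…R: draw n residuals from ε̂ iid with replacement, set
   y*ᵣ = μ*(δ) + ε*ᵣ, refit, and record whether the trend test rejects at α.
4. Power = (#rejections)/R, with Monte-Carlo SE √(p̂(1−p̂)/R).

Residuals are resampled across the whole window rather than within site or
in blocks: the Durbin–Watson/FDR screen finds autocorrelation in only a
small minority of site-analyte series, and the spatial screen of the
original analyses found none, so the iid scheme is the defensible default.
Stratified or block schemes would be the first extension if those
diagnostics changed.

Defaults: δ grid −0.20…0.20 in steps of 0.01 (41 points), R = 1000,
α = 0.05, classical inference inside the bootstrap (HAC/cluster variants are
one config switch and reproduce the robust-inference sensitivity analyses).
Each δ uses a child random stream derived from (seed, δ), so a curve is
reproducible and independent of evaluation order. Because the design matrix
is identical across replicates, the classical path is vectorised: one
pseudoinverse, then matrix products over an n×R response matrix; robust
paths refit per replicate. The headline summary averages power at δ = ±0.1;
design comparison further averages the three pre-2015 windows before
comparing against the post-2015 window.

## Synthetic monitoring data

The generator reproduces what matters statistically about the monitoring
program, not its oceanography:

- **Calendars.** Each site-year is split into wet (Nov–Apr) and dry
  (May–Oct) seasons by calendar month; k visits per season occupy k evenly
  spaced slots with the day jittered uniformly inside each slot, so every
  fully covered calendar year holds exactly the configured counts (the
  published calendars give only per-season annual counts, so any placement
  honouring them is admissible — this one reproduces the roughly
  twice-monthly-to-monthly wet-season cadence). Packaged specs encode both
  eras: 10 sites at 1 wet + 2 dry visits (2005–2014) and 22 sites at
  region-specific frequencies (February 2015 – mid-2019), with visits at
  shared sites rotating between the two institutions so institution effects
  remain estimable alongside site effects.
- **Measurements.** Each visit yields surface and bottom layers with (by
  default two) duplicates per layer. The log-scale value is the model's
  linear predictor plus visit-level N(0, σ²) noise shared across layers,
  plus optional depth offset and per-duplicate noise — within-visit
  structure the trend model never sees because preparation averages it away.
  Concentrations are the exponential, so values are guaranteed positive.
- **Censoring.** Values below a detection limit are flagged and stored at
  half the limit (the 1/2DL convention of the source database); the packaged
  NOx parameters include a limit so the below-detection path is always
  exercised. Alternative substitution fractions are a config hook only.
- **Defaults.** Per-analyte generating values (log-intercepts near typical
  inshore concentrations, residual SDs 0.4–0.8, a wet-season-peaked
  harmonic, a 0.1 institution offset) are fixed in
  `pipeline.DEFAULT_ANALYTE_PARAMS` and were chosen once as field-realistic;
  they are the package's study conditions, not tuning knobs.

What the generator deliberately omits: flood-plume events, spatial
correlation between sites, serially correlated errors, and non-lognormal
heavy tails. Passing tests therefore demonstrate that the machinery is
correct under the model's own assumptions and realistic designs — not that
real reef data satisfy those assumptions; the Durbin–Watson/FDR and robust-
covariance options exist precisely to check and hedge that gap on real data.

## Data preparation

Fixed order: average duplicates within (site, date, analyte, depth) →
average surface and bottom → (censoring was applied upstream) → drop
configured (analyte, institution) exclusions (by default NOx from the second
institution, whose analytical method differs) → restrict to a window →
log-transform. With balanced duplicates the two averaging steps commute;
with unbalanced ones the fixed order defines the estimand. Depth averaging
refuses input with multiple rows per layer, which signals that replicate
averaging was skipped.

The four packaged comparison windows are encoded exactly as published,
including bound inclusivity (S1 open/open, S2 closed/open, S3 closed/closed,
post-2015 open-left, no upper bound). S1 and S3 span 1564 and 1559 days; the
S2 bounds span 1661 days — the ~1550-day equivalence of the three pre-2015
periods refers to the data coverage inside the windows, which the simulated
calendars (ending in late 2014) reproduce.

Scenario subsampling thins each post-2015 site-year back to the sparse
cadence by keeping the visit nearest the midpoint of one wet and two dry
target slots (the sparse calendar's own slot positions), ties broken by the
earlier date. The rule is deterministic, makes each scenario a strict row
subset of the input, and nests: null ⊆ null+sites, null ⊆ null+samples ⊆
current. Site-years with fewer visits than the target keep everything, with
a warning.

## Time to exceedance

For δ ≠ 0 the projected level m(1+δ)^t crosses a bound q at exactly
t = ln(q/m)/ln(1+δ) years (0 if already crossed). The starting level m is
each site's geometric mean of post-2015 values — the natural-scale central
tendency consistent with a log-scale model (arithmetic mean is an option);
bounds are the pooled area-level empirical 10th/90th percentiles
(linear-interpolation quantiles, the common default). Rising trends are
compared against q90, declines against q10; the area summary is the
arithmetic mean of per-site times. Times are scale-invariant and
non-increasing in |δ|.

## Numerical and design choices

- Rank checks: the design matrix must be full column rank; aliased columns
  are identified greedily and named in the error.
- Seeds: one top-level integer; every stage and δ derives an independent
  `numpy` child stream from (seed, stage key), so outputs are byte-stable
  under rerun and independent of execution order.
- Degenerate inputs are refused loudly rather than patched: non-positive
  values at the log step, all-zero residuals in Durbin–Watson, fewer than 10
  values for percentile bounds, n ≤ p fits, single-cluster robust inference,
  δ ≤ −1 anywhere, δ = 0 in exceedance.
- Pipeline cells fail independently: one analyte × area error is logged and
  the rest proceed, matching per-combination reporting.

## Problem sizes

The shipped analysis scripts and the acceptance script run the full design
comparison at the ±0.1 grid points with R = 300–1000 and the validation
studies at 50–200 simulated datasets; these sizes give Monte-Carlo errors of
1–3 percentage points on power estimates, which is ample for the
directional and calibration claims made, and keep any run to tens of
seconds. The full 41-point curves at R = 1000 are one config change
(`power.delta_grid`) and scale linearly.

## Known limitations

- Power is for a sustained log-linear trend; changepoints, pulses, or
  nonlinear recovery trajectories are out of scope.
- The bootstrap inherits the fitted model: misspecified seasonality or
  heteroskedasticity propagate into the pseudo-data (robust inference
  options mitigate only the testing step).
- Exceedance projections are point summaries with no uncertainty interval.
- The generator's independence assumptions mean design comparisons quantify
  sampling-effort effects, not spatial-redundancy effects between nearby
  sites.
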