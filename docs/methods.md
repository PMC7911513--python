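# Methods

This note documents the models behind `platekd`: what the forward
simulator emulates, how the analysis estimators work, which defaults
matter, and where the design was genuinely open.

## Plate geometry and acquisition

A 384-well plate is a 16×24 grid, rows A–P and columns 1–24
(0-based internally, lettered/1-based in every file).  Edge wells are
rows A/P plus columns 1/24 — 76 wells; the remaining 308 are center
wells.  Rows are additionally grouped into bands (upper A–E, middle F–K,
bottom L–P by default; configurable) because the reader visits wells in
row-major order, so bottom-band wells are measured hours after the run
starts and have evaporated longest.

The acquisition schedule assigns well *i* the elapsed start time
`i · dwell`.  The per-well dwell defaults to 75 s, the value at which the
recommended layouts' first-to-last read times come out at 5 h for
240 wells and 6.25 h for 300 wells.  The nominal measurement protocol
(15 acquisitions of 15 s) accounts for 225 s per well, so the 75 s
default implies either parallel settling/positioning overheads or
shortened acquisitions; instrument auto-attenuation also makes real
end times plate-dependent.  This tension cannot be resolved from the
available descriptions, so the dwell is an explicit configuration scalar
rather than something derived from the acquisition settings.

`validate_layout` screens layouts against the rules that the variability
analysis supports: no samples in edge wells, at least 5 replicates per
concentration (so one outlier can be spared), at least 3 concentration
steps (the high-quantity reference design uses exactly 3; 4 or more is
preferable when API permits), and low concentrations never placed in
lower (later-read) rows than high concentrations of the same
formulation, compared by mean row index.

## Forward model

### Diffusion

Each formulation carries a ground truth `(D0, kD, R_H)` with `D0`
consistent with `R_H` through Stokes–Einstein at the simulation
temperature.  A well at effective concentration *c* (g/mL) diffuses with
`D = D0 (1 + kD c)`; configurations with `1 + kD c ≤ 0` are rejected as
unphysical.

### Evaporation

Well volume decays linearly in time,

```
V(t)/V0 = max(floor, 1 − r · e_well · j_well · j_run · exp(−c0/s) · t_hours)
c(t) = c0 · V0 / V(t)
```

with solute mass conserved exactly until the volume floor engages.
Parameters and defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `base_rate_per_h` | 0.0338 | fractional volume loss per hour, dilute center well |
| `edge_factor` | 2.0 | multiplier `e_well` for edge wells |
| `suppression_scale_mg_ml` | 3.0 | concentration scale `s` of evaporation suppression |
| `min_volume_fraction` | 0.3 | V/V0 floor (10 µL of a 30 µL fill) |
| `rate_jitter_sd` | 0.2 | lognormal sigma of per-well rate jitter `j_well` |
| `run_factor_sd` | 0.3 | lognormal sigma of the per-run ambient factor `j_run` |

The base rate is calibrated so that a 2 mg/mL lysozyme-like sample
(kD = 91.8 mL/g) in a center well read at the end of a full-plate run
(384 wells × 75 s = 8 h) shows a 2.5% apparent increase of D.  With the
suppression scale at 3 mg/mL the same calibration puts the drift of 10
and 14 mg/mL wells at a few tenths of a percent, reproducing the
qualitative ordering (dilute wells drift most) though not every reported
decimal.  Linear-in-time loss is the simplest model compatible with the
observed monotone drift; no attempt is made to model Marangoni or
capillary flows mechanistically.  The two lognormal terms emulate local
airflow differences between wells and ambient (humidity/temperature)
differences between runs; they are what gives edge-well-heavy layouts
their larger run-to-run kD variance, since a deterministic drift alone
would only bias, not scatter.

### ACF synthesis

A well measurement is an intensity autocorrelation function on a
64-point log-spaced lag grid (1 µs – 1 s),

```
g2(τ) = 1 + β [(1−f) e^{−Γ1 τ} + f e^{−Γ2 τ}]² + ε(τ)
```

with `Γ = D q²`, `q = (4πn/λ) sin(θ/2)`, coherence factor β = 0.25, and
i.i.d. Gaussian noise of SD `noise_sigma0 / sqrt(n_acquisitions)`.
Instrument defaults describe a near-backscatter 830 nm reader
(θ = 158°, n = 1.331, T = 298.15 K, η = 0.8872 mPa·s, 15 × 15 s
acquisitions); they are configuration, never hard-coded in the math.
`noise_sigma0 = 0.006` (per-point SD ≈ 1.5 × 10⁻³ after averaging) is
calibrated so that per-well diffusion coefficients come out with ≈ 1.7%
median relative error, matching the ≈ 2% intra-plate D variability that
well-run plate measurements show.  Second particle populations
(soluble aggregates) are injected as a two-exponential mixture with
radius drawn from Normal(42.8, 7.9²) nm at 11.6% intensity fraction by
default; gross per-well outliers multiply D by a lognormal factor.
Everything is reproducible from `(layout, parameters, seed)`.

Control/placebo wells contain solvent only and produce flat noise ACFs;
the analysis flags them as failed fits rather than dropping them, so
batch bookkeeping stays complete.

## ACF analysis

### Cumulant fit

The second-order cumulant estimator fits
`ln(g2 − 1) = ln β − 2Γτ + μ₂τ²` by weighted least squares with weights
proportional to the signal (the delta-method optimum for log-transformed
noise).  The fit window keeps the leading run of lags with
`g2 − 1 > 0.05 β̂` (crude `β̂` from the first three lags), which avoids
taking logs of noise-dominated tail points; with the default grid and a
1.9 nm particle that is ≈ 16 lags.  Outputs: Γ, β, μ₂,
`PDI = max(μ₂, 0)/Γ²`, `D = Γ/q²`, the long-lag baseline (mean of the
last quarter of lags), and `SOS` — the window residual sum of squares
divided by the tail-estimated noise variance, a dimensionless
goodness-of-fit in the spirit of plate-reader software quality gates.
For a well-described single-exponential decay SOS ≈ the window size
(≈ 10–16); fits are flagged when SOS ≥ 20, when the baseline leaves
[0.997, 1.003], or when PDI > 0.3.  All thresholds are configurable.
A signal with no positive leading window raises an explicit fit error.

### Regularized inversion

The size distribution solves a non-negative Tikhonov problem

```
min_{w ≥ 0}  ‖W (A w − s)‖² + λ² ‖L w‖²
```

on a 60-point log radius grid (0.5–500 nm), where
`A_ij = exp(−Γ_j τ_i)` with `Γ_j` from the grid radii via
Stokes–Einstein, and `s = sign(g2−1)·sqrt(|g2−1|)` is the field
correlation amplitude.  Two numerical choices matter and were made after
observing failure modes of the naive formulation:

* the **signed** square root keeps tail noise zero-mean — clipping at
  zero before the square root rectifies noise into a positive bias that
  materializes as phantom mass at large radii;
* the weights `W` come from delta-method error propagation
  (`var(s) ≈ σ²/4y`) with the denominator floored at `3σ`, because
  unfloored data-dependent weights overweight positive noise excursions
  and again bias the tail.

`L` is a second-difference operator with zero boundary conditions
(mass is penalized for piling up at the grid ends); an identity operator
is available.  The default λ = 0.01 resolves a 42.8 nm population at
11.6% intensity next to a 1.9 nm monomer at the default noise level,
with the peak position scattering over roughly a factor of two around
the truth — peak *detection* is reliable, peak *location* of a minority
population inherits the ill-conditioning of inverse Laplace transforms.
Peaks are contiguous runs of grid mass ≥ 1% of the total, summarized by
intensity-weighted geometric-mean radius; fractions are reported in
scattered-intensity space with no volume/number conversion.  The
commercial regularization settings this mirrors are not public, so
equivalence is claimed at the level of peak positions and fractions
only.

In plate analysis the inversion runs on demand or automatically when
the cumulant PDI exceeds 0.1, and a well is flagged `multimodal` when a
second peak carries ≥ 5% intensity.

## kD pipeline

Per-well diffusion coefficients are grouped by concentration and
screened with an iterative two-sided single-outlier Grubbs test
(α = 0.05): `G = max|xᵢ − x̄|/s` against
`G_crit = ((n−1)/√n)·sqrt(t²/(n−2+t²))`, `t` the upper `α/(2n)` Student-t
quantile with `n−2` df, removing at most `max_removals = 2` points per
group (five replicates are recommended precisely so one outlier can be
spared; two removals cover the observed worst case).  Groups smaller
than 3 pass through untested but flagged; zero-variance groups report
"no outlier".  Kolmogorov–Smirnov normality checks run per group before
screening — note that KS with parameters estimated from the data is
conservative; `ks_normality` accepts fixed reference parameters when the
nominal level matters.  Variance homogeneity is checked by pairwise
two-sided F-tests.

The fit itself is unweighted OLS of D on c (concentrations converted to
g/mL internally so kD·c is dimensionless with kD in mL/g; plate files
stay in mg/mL), `D0 = intercept`, `kD = slope/intercept`, with standard
errors for both and a delta-method SE for kD.  Raw and screened variants
are both available.  Fewer than two distinct concentrations or a
non-positive fitted D0 raise explicit errors.  Grubbs screening is
applied per concentration group, not to pooled residuals; a pooled
variant was considered and rejected because the replicate group is the
natural exchangeable unit.

`extrapolate_rh0` fits apparent R_H against concentration inside a
configurable window (default 2–7 mg/mL) and reports the intercept
R_H(c→0).  Because apparent R_H(c) = R0/(1 + kD c) is only near-linear
for moderate kD·c, the linear extrapolation carries a curvature bias for
strongly interacting samples; the window should be kept narrow in that
regime.

## Variability statistics

* `cv`: 100·SD/|mean| with sample SD; a zero mean is an explicit error
  (near-zero means produce the CV blow-ups seen for kD ≈ 0, e.g.
  CV > 150% at kD = −1 mL/g in the Monte-Carlo below).
* `pooled_intra_cv`: pooled within-group SD
  `sqrt(Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1))` over the grand mean of all contributing
  values ("overall mean" is not defined more precisely anywhere, so the
  grand mean was chosen and documented); `average_intra_cv` averages
  per-run pooled CVs arithmetically, and both orders of
  pooling-vs-averaging are computable.
* one-way ANOVA by the standard between/within decomposition, reporting
  F, F_crit(α = 0.05), and p, with significance under the double rule
  `F > F_crit and p ≤ α`; repeated-measures ANOVA as the two-factor
  without-replication decomposition with the run factor as the
  consistency test.
* post-hoc pooled-variance t-tests with Bonferroni adjustment by
  default — the correction method behind historical spreadsheet
  analyses is unknowable, and Bonferroni is the conservative choice;
  configurable.
* `span_kd`: range-based dispersion of single-kD estimates.  The
  primary definition is `100·(max − min)/|min|`, which reproduces the
  reference total span (39.0% vs the reported 39.2% from extremes 47.4
  and 65.9 mL/g, the residual being rounding of the printed extremes).
  Range-over-reference and range-over-mean are selectable, and the
  output always labels the definition used, because no definition
  reproduces every reported span figure (the phosphate-buffer spans are
  mutually inconsistent under all three candidates — e.g. extremes
  −14.1/−15.8 mL/g cannot yield 37.6% under any of them).
* `summarize_approaches` emits the machine-readable approach table
  (mean, SD, counts, points per kD, CV, span, plus an all-values total
  row).

All of these are cross-checked in the test suite against brute-force
arithmetic and against independent implementations
(`scipy.stats.f_oneway`, `ttest_ind`) to 1e−10.

## Layout designs and budgets

`recommended_design` builds two deterministic screening layouts, both
keeping all 76 edge wells sample-free, low concentrations in early-read
rows, and vertical replicate runs:

* **low_risk**: 8 formulations × 5 concentrations (2, 4, 6, 8,
  10 mg/mL) × 6 replicates = 240 wells filling rows B–M, columns 3–22
  (read B3 → M22, 5 h at 75 s/well); 43.2 mg API at 30 µL/well, inside
  a 44 mg budget.
* **high_quantity**: 20 formulations × 3 concentrations (2, 5,
  10 mg/mL) × 5 replicates = 300 wells (read B2 → O21, 6.25 h);
  51.0 mg API (a nominal 50 mg budget rounds this).  Geometric note:
  300 wells of strictly vertical 5-replicate runs cannot fit in the 14
  non-edge rows (two 5-row bands leave only 4 rows), so the encoding
  uses 44 vertical runs in bands B–F/G–K plus 16 horizontal 5-replicate
  runs in rows L–O — which is exactly what reproduces the B2 → O21
  read span.

An optional buffer fill writes placebo wells into rows A and P for
thermal insulation.  `api_budget` sums concentration × fill volume per
well exactly (`math.fsum`); budgets are reproducible to the last bit and
regeneration is byte-identical.

`build_paper_layouts` encodes the reference experimental designs: the
intra-plate lysozyme plate (8-step horizontal series, 5 replicate rows),
the inter-plate plate (4 concentrations × 5 replicates × 3 position
bands, controls in row P; 3 positions × 3 runs = 9 single-kD fits per
batch), and the eight approach groupings A–H for both buffer systems.
The approaches share one physical 240-well plate (8 blocks of 6
replicate rows × 5 concentrations, bands A–F/K–P, column groups 1–5,
6–10, 15–19, 20–24) and differ only in how wells are grouped into
single-kD fits: A = the 8 blocks (30 points each), B = the two 120-point
bands, C/D = 64/64/56/56-point splits ordered by proximity to the plate
edge (C, row-first) or to the edge columns (D), E/F = four 30-point
groups from the most-edge (E) or most-central (F) replicates, G =
horizontal three-row groups and H = vertical column groups (60 points
each) — 34 single kD values in total.  Only the group sizes and the
edge/center/orientation character of each approach are fixed by the
published record; the exact well membership is this package's
deterministic interpretation.

`monte_carlo_design_eval` scores any layout by repeated
simulate → analyze → screen → fit cycles and reports mean, SD, CV and
bias of k̂D per group.  Under default conditions the edge-heavy 30-point
grouping (E) shows roughly twice the kD CV of the center 120-point
grouping (B), reproducing the reference ordering.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses a 25-well single-formulation plate
(5 concentrations × 5 replicates) for the 500-plate Monte-Carlo of kD
recovery, 200 simulated runs of the shared 240-well approach plate for
the E-vs-B comparison, 10,000 random datasets for the Grubbs oracle
check, and 1,000 contaminated fits for the screening-improves-R² rate —
sizes chosen so the whole script completes in about two minutes on one
CPU while keeping every Monte-Carlo margin far from its threshold.

## What passing tests do and do not show

The simulator reproduces the statistical *structure* the analysis
assumes: Eq.-style linear D(c), monotone position- and time-dependent
evaporation, homoscedastic ACF noise, occasional aggregates and gross
outliers.  It does not emulate auto-attenuation (laser power changes
between wells), multiple scattering, viscosity-dependent decay-rate
changes within a well (a linear η(c) hook exists but defaults to off),
meniscus optics, or robot pipetting errors with spatial structure.
Parameter-recovery results therefore validate the estimators and the
relative ranking of layouts under the modelled error budget; they do not
certify absolute CV values for any particular instrument.  Measured kD
values from the original experiments were never deposited, so recovery
is demonstrated against simulated ground truth, not against the
published point estimates.
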