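# Methods

## The estimand and the model

The package estimates conditional quantile curves
Q_y(τ | sex, age[, height]) of FEV1 (liters) and BMI (kg/m²) in a CF
population, for τ = 0.01 … 0.99, and inverts them to rank individual
measurements against their peers.  Quantile regression is the natural
tool: it models each percentile directly, makes no distributional
assumption about the residuals, and is fitted independently per τ by
minimizing the pinball loss ρ_τ(r) = r(τ − 1{r<0}).

Nonlinearity in age and height is captured by cubic B-spline bases.
"Six nodes" is implemented as six *knots* — the two boundary knots at
the training min/max plus four interior knots at equally spaced
quantiles (0.2, 0.4, 0.6, 0.8) of the covariate — giving a basis of
dimension 8.  This is deliberately stiff: percentile charts must not
chase local wiggles.  Both the node count and their placement rule are
recorded in the chart metadata and configurable, because "node" is
ambiguous between knots and basis functions; results are insensitive to
the reading at these sample sizes.

The age+height model is **additive**: full spline basis in age (its
partition of unity supplies the intercept) plus a height basis with the
first column dropped to avoid collinearity.  A tensor-product surface
was rejected as the default: the additive form matches common practice
for spirometry references, needs an order of magnitude fewer
coefficients, and the strong age–height collinearity of growing
children leaves little data to identify an interaction.

Each fit solves the LP

    min_{β,u,v} τ·1ᵀu + (1−τ)·1ᵀv   s.t.  Xβ + u − v = y,  u,v ≥ 0,

in its dual form (max yᵀd, Xᵀd = 0, d ∈ [τ−1, τ]) with HiGHS; the dual
has only p equality constraints instead of n, which is ~20–40× faster
at registry scale, and strong duality makes the achieved losses
identical.  β is recovered from the equality-constraint marginals.
Minimizers can be non-unique (quantile fits interpolate data points),
so tests compare achieved loss, never coefficients; observed
reproducibility of the optimum across equivalent solves is ~1e−6
relative.

### Crossing and rank lookup

Independently fitted quantile curves may cross in finite samples.
Before inversion the 99 values at the query covariate point are sorted
(monotone rearrangement), which is loss-free at points where the fits
are already ordered and guarantees a well-defined inverse elsewhere.
The percentile rank is the linear interpolation in τ between adjacent
rearranged curve values, clamped to [1, 99]; values outside are flagged
`<1st` / `>99th` by the CLI.  No extrapolation beyond the training
covariate range is allowed by default; `extrapolate=True` evaluates the
spline's polynomial tails instead (with the caveat that tail behaviour
is unsupported by data).

### Analysis filters

Post-transplant measurements are removed for all analyses; FEV1
analyses keep ages [6, 40] (closed interval), BMI analyses ages
[0, 40].  Filters are recorded in registry provenance and chart
metadata.

## Best-annual-value correction

Some registries report the year's highest FEV1; fitting charts to such
data overstates the reference curves for patients assessed from
ordinary visits.  Using visit-level longitudinal data, the correction
table holds, per sex × age band ([6,10), [10,15), [15,20), [20,30),
[30,40] by default, configurable), the mean of max(visits) −
mean(visits) over patient-years with ≥ 2 visits — i.e. the expected
excess of the best value over a uniformly drawn unselected visit.  A
seeded variant draws one random visit instead.  Best-type records have
their band delta subtracted (floored at 0.05 L) and are relabelled
`corrected` before fitting; unselected records pass through.  Empty
bands are flagged missing and raise if a record needs them.

## Bootstrap inference

The resampling unit is always the **patient** — all records of a
resampled patient enter together — which is the conservative choice
under repeated annual measurements.  Pointwise confidence bands refit
the τ-curve on B = 200 resamples (knots re-placed each time, as a full
refit would) and take percentile envelopes.  The AUC test integrates
the difference of two independently fitted curves over a common grid
(trapezoid rule) and resamples both registries independently
(B = 999 by default); the two-sided p-value recenters the bootstrap
distribution at the observed statistic,
p = (1 + #{|d* − d| ≥ |d|}) / (B + 1).  Recentering is an
interpretation choice (the alternative — treating the pooled data as
the null — couples the two samples); it is the standard percentile
bootstrap test and its type-I error is verified by simulation in the
test suite.  Group median-percentile CIs use level 1 − α/m with
m = groups × age classes (12 for 4 groups × 3 classes), and a cell is
flagged when 50 lies outside its CI.  Age classes: infants [2,6),
children [6,13), teenagers [13,20), adults ≥ 20 years.  Medians of
even-count samples are the midpoint of the central pair.  All
procedures are deterministic given their seed.

## Healthy-population referencing

Percent predicted FEV1 uses sex/age-stratified linear equations
(intercept + age + height), evaluated with no smoothing across stratum
boundaries — the discontinuities are a documented property of this
classical family of references.  BMI z-scores use the LMS method with
linear interpolation of (L, M, S) in age and no extrapolation.  Both
engines read CSV coefficient tables with schema checks.  **The bundled
tables are synthetic stand-ins** (`*_synthetic.csv`, marked as such in
their headers): they have the exact schema and realistic magnitudes but
are not transcriptions of any published standard, so that no
unverifiable numbers masquerade as Knudson or WHO coefficients.  For
clinical use, point the loaders at files transcribed from the published
sources.

## The synthetic registry

The generator produces the study conditions the pipeline assumes, with
closed-form ground truth:

* **FEV1**: log-normal around a median surface
  m(sex, age, height) = f_age(sex, age) · (1 + β(height − h_med(age))),
  clamped positive.  f_age rises from 1.0 L at age 6 (both sexes) along
  a monotone cubic Hermite arc to a sex-specific peak — 3.0 L at 18 y
  (males), 2.3 L at 16 y (females) — then declines linearly (0.030 and
  0.022 L/year).  β = 0.01/cm gives ≈ 0.25–0.3 L per 10 cm near the
  peak.  The marginal log-SD is σ = 0.32, chosen so the interquartile
  range at the male peak spans roughly 2.4–3.7 L.  The closed-form
  quantile is m·exp(σ·Φ⁻¹(τ)).
* **Visits**: each patient-year draws k visits (default 3) sharing a
  patient-year effect: log FEV1 = log m + σ_b·Z + σ_w·ε, with σ_w = 0.07
  and σ_b² = σ² − σ_w².  A single visit is therefore exactly
  log-normal(log m, σ) — the oracle is untouched — while the best of k
  exceeds an unselected visit by a realistic 0.1–0.2 L.  Making visits
  fully independent instead would equate within-year and population
  variability and produce an absurd ~1 L selection bias.
* **Heights**: Gaussian around a per-sex median growth curve
  interpolated through landmark (age, height) pairs (birth ≈ 50 cm,
  pubertal spurt, adult plateau at 177/163 cm); SD 6 cm at adult
  height, shrunk pro rata in children.  This produces the strong
  age–height collinearity that stresses the additive model.
* **BMI**: drawn exactly from configurable per-sex LMS curves whose
  medians dip after infancy, rebound, and plateau below a healthy adult
  reference — the post-childhood deficit typical of CF.  The closed
  form is the LMS inverse M(1 + L·S·Φ⁻¹(τ))^{1/L}.
* **Countries**: France and Germany (60% of patients) report unselected
  visits; smaller high- and low-coverage groups report best values.
  Weights and reporting flags are configurable, so inter-country
  comparisons can be simulated under the null or under shifts.
* Ages uniform on [0, 40]; FEV1 only from age 6; 2% of patients carry a
  transplant flag (their records exist and are removed by the filters,
  as in the real pipeline); genotype is 48% F508del-homozygous.

What the generator does **not** emulate: within-patient correlation
across calendar years (each patient-year effect is independent),
mortality/attrition (so no survivor bias builds into older ages),
missingness beyond the under-6 spirometry gap, measurement error in
height/weight, and secular trends.  Passing tests therefore demonstrate
that the machinery recovers known truth under clean conditions, not
that real registry artefacts are handled.

## Problem sizes and numerical choices

The heavier simulation checks run at deliberately chosen scales: chart
calibration and coverage at 5,000 patients/sex, parameter recovery at
20,000, bootstrap band coverage over 100 replicate registries of 2,000
patients (B = 200), and the AUC test's null rejection rate over 500
paired registries of 120 patients (B = 99) — sizes at which the
properties under test are informative while the full suite stays
practical to run routinely.  Spline knots collapse duplicates on
heavily tied data; rank-deficient designs and underdetermined fits
raise informative errors rather than returning garbage.  LP optimality
is asserted to 1e−9 against brute force on intercept-only problems and
to solver tolerance (~1e−6 relative) between equivalent general fits.

## Known limitations

* Quantile curves are fitted independently per τ; there is no joint
  smoothing across levels (rearrangement handles crossing at lookup).
* Percentiles are cross-sectional and not survival-adjusted: ranking
  50th at age 8 and at age 40 are different achievements because of
  differential attrition, which this machinery does not correct.
* The bundled healthy-reference tables are synthetic; conclusions about
  distance-to-normality require substituting published coefficients.
* The additive age+height model cannot represent age-varying height
  effects; a tensor-product option would be the natural extension.
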