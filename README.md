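# cfcentiles

Disease-specific reference percentile charts for cystic fibrosis (CF)
lung function and nutrition.

CF care conventionally references a patient's FEV1 (forced expiratory
volume in one second, liters) and BMI against *healthy* populations —
percent predicted FEV1 and BMI z-scores.  Those numbers say how far a
patient is from normality, but not where they stand **among CF peers of
the same sex, age and height**, which is what clinicians need for
center-to-center comparison, trial stratification, and tracking a
patient relative to others receiving comparable care.  `cfcentiles`
builds such disease-specific percentile charts from registry data and
ranks individual measurements against them.

## Method

For each sex and percentile level τ ∈ {0.01, …, 0.99}, the conditional
quantile of the outcome y (FEV1 or BMI) is modelled as

    Q_y(τ | x) = B(x)ᵀ β_τ

where B(x) is a cubic B-spline basis in age (and, additively, in height)
with 6 knots — boundary knots at the data range, interior knots at
equally spaced quantiles of the covariate.  Each β_τ minimizes the
pinball (check) loss Σ ρ_τ(y_i − B(x_i)ᵀβ), solved exactly as a linear
program (HiGHS, via the dual).  Around the fitted family:

* **Best-annual-value correction** — registries that report the year's
  *best* FEV1 rather than an arbitrary visit bias the curves upward;
  the sex × age-band mean excess of best over unselected values is
  estimated from visit-level longitudinal data and subtracted before
  fitting.
* **Rank lookup** — the 99 curves are monotonically rearranged at the
  query point and inverted to give an individual's CF-specific
  percentile (clamped to [1, 99]).
* **Inference** — pointwise bootstrap confidence bands (patients
  resampled with replacement), a bootstrap test on the difference in
  area under two charts' curves, chart-vs-chart correlation, and
  Bonferroni-adjusted bootstrap CIs for group median percentiles.
* **Healthy referencing** — Knudson-style linear prediction equations
  and LMS ((x/M)^L − 1)/(L·S) z-scores, table-driven and pluggable (the
  bundled tables are clearly labelled synthetic stand-ins; substitute
  published coefficient files for clinical use).
* **Synthetic registry** — a seeded generator with closed-form
  conditional quantiles (log-normal FEV1 around a sex/age/height median
  surface; LMS-based BMI) that emulates the structure of a multinational
  CF registry, including repeated within-year visits and best-value
  reporting countries.

## Worked example

```python
from cfcentiles import (SimConfig, SplineSpec, simulate_registry,
                        filter_registry, fit_chart,
                        load_default_prediction_equations,
                        predicted_fev1, percent_predicted)

config = SimConfig(n_patients_per_sex=4000, seed=11)
registry = filter_registry(simulate_registry(config), "fev1")
chart = fit_chart(registry, "fev1", "M", ("age", "height"),
                  specs={"age": SplineSpec(), "height": SplineSpec()})

rank = chart.percentile_rank(3.0, age=20.0, height=170.0)
pred = predicted_fev1(load_default_prediction_equations(), "M", 20.0, 170.0)
print(f"CF-specific percentile: {rank:.0f}")
print(f"percent predicted: {percent_predicted(3.0, pred):.0f}%")
```

prints

```
CF-specific percentile: 56
percent predicted: 79%
```

A 20-year-old male of 170 cm with FEV1 = 3.0 L sits at the 56th
percentile *among his (synthetic) CF peers* while being at 79% of the
healthy-reference prediction: the two reference frames answer different
questions.  The same chart evaluated at that covariate point gives the
percentile curves themselves, e.g. 2.84 L (median) and 1.72/4.86 L (5th
and 95th percentiles).

The same pipeline is scriptable from the shell:

```bash
cfcentiles simulate --n 4000 --seed 11 --out registry.csv --longitudinal-out visits.csv
cfcentiles correct  --registry registry.csv --longitudinal visits.csv --out corrected.csv
cfcentiles fit      --registry corrected.csv --sex M --covariates age+height --out chart_M.json
cfcentiles score    --chart chart_M.json --chart chart_F.json --registry corrected.csv --out scored.csv
```

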