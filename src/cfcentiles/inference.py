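"""Bootstrap inference for percentile charts.

Pointwise confidence bands for quantile curves, a bootstrap test on the
difference in area under two charts' tau-curves, Pearson correlation
between two charts over a tau × covariate lattice, and Bonferroni-adjusted
bootstrap confidence intervals for group median percentile ranks.

The resampling unit is always the PATIENT: all of a patient's records move
together, which is conservative under repeated annual measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .charts import FitError, PercentileChart, SplineSpec
from .registry import Registry, ValidationError

#: age classes of the inter-country comparison (labels -> [lo, hi) years)
AGE_CLASSES = {
    "infants": (2.0, 6.0),
    "children": (6.0, 13.0),
    "teenagers": (13.0, 20.0),
    "adults": (20.0, float("inf")),
}


def age_class(age: float) -> str | None:
    """Age-class label; None below 2 years."""
    for label, (lo, hi) in AGE_CLASSES.items():
        if lo <= age < hi:
            return label
    return None


@dataclass
class BootstrapBand:
    """Pointwise percentile envelope of a fitted quantile curve."""

    tau: float
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    B: int
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.lower > self.estimate + 1e-9) or np.any(
            self.upper < self.estimate - 1e-9
        ):
            warnings.warn(
                "point estimate outside bootstrap envelope at some grid points",
                stacklevel=2,
            )


@dataclass
class TestResult:
    """A statistic with its bootstrap CI and (optionally) p-value."""

    label: str
    statistic: float
    ci: tuple[float, float]
    p_value: float | None = None
    B: int = 0
    seed: int = 0
    adjustment: str = "none"
    flagged: bool = False
    n: int = 0


def _resample_patients(registry: Registry, rng: np.random.Generator) -> Registry:
    groups = registry.patient_indices
    ids = np.fromiter(groups.keys(), dtype=object, count=len(groups))
    draw = rng.choice(ids, size=len(ids), replace=True)
    idx = np.concatenate([groups[p] for p in draw])
    return registry.with_frame(registry.frame.iloc[idx])


class _CurveBootstrap:
    """Array-level patient bootstrap of a single tau-curve.

    Pulls the (covariates, outcome, patient) arrays out of the registry
    once; each replicate resamples patients with replacement, refits the
    spline knots on the resampled covariates (as a refit from scratch
    would) and solves the quantile LP.  Covariates beyond the first are
    held at their full-sample median when evaluating on the grid.
    """

    def __init__(
        self,
        registry: Registry,
        outcome: str,
        sex: str,
        covariates: Sequence[str],
        tau: float,
        n_nodes: int,
        grid: np.ndarray,
    ) -> None:
        self.covariates = tuple(covariates)
        self.tau = float(tau)
        self.n_nodes = n_nodes
        self.grid = np.asarray(grid, dtype=float)
        frame = registry.frame[registry.frame["sex"] == sex]
        if frame.empty:
            raise FitError(f"no records for sex {sex!r}")
        colmap = {"age": "age_years", "height": "height_cm"}
        self.x = {c: frame[colmap[c]].values.astype(float) for c in self.covariates}
        if outcome == "fev1":
            y = frame["fev1_l"].values.astype(float)
        else:
            y = (frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2).values
        if np.any(np.isnan(y)):
            raise FitError("missing outcome values; filter the registry first")
        self.y = y
        pid = frame["patient_id"].values
        _, inv = np.unique(pid, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        bounds = np.flatnonzero(np.diff(inv[order], prepend=-1))
        self.patient_rows = np.split(order, bounds[1:])
        self.n_patients = len(self.patient_rows)

    def resample(self, rng: np.random.Generator) -> np.ndarray:
        draw = rng.integers(0, self.n_patients, size=self.n_patients)
        return np.concatenate([self.patient_rows[i] for i in draw])

    def fit(self, idx: np.ndarray | None = None, check_rank: bool = False) -> np.ndarray:
        """Curve values on the grid from a (re)fit on rows ``idx``."""
        from .charts import _build_design, fit_quantile

        sel = slice(None) if idx is None else idx
        xs = {c: v[sel] for c, v in self.x.items()}
        ys = self.y[sel]
        specs = {
            c: SplineSpec(n_nodes=self.n_nodes).fit_knots(xs[c])
            for c in self.covariates
        }
        X = _build_design(specs, self.covariates, xs)
        if len(ys) < X.shape[1]:
            raise FitError(f"{len(ys)} rows < design dimension {X.shape[1]}")
        if check_rank and np.linalg.matrix_rank(X.toarray()) < X.shape[1]:
            raise FitError("rank-deficient design; use fewer spline nodes")
        coef = fit_quantile(X, ys, self.tau)
        cov0 = self.covariates[0]
        lo, hi = specs[cov0].boundary
        gvals = {cov0: np.clip(self.grid, lo, hi)}
        for c in self.covariates[1:]:
            clo, chi = specs[c].boundary
            gvals[c] = np.full(
                self.grid.shape, np.clip(np.median(self.x[c]), clo, chi)
            )
        G = _build_design(specs, self.covariates, gvals)
        return np.asarray(G @ coef)


def bootstrap_band(
    registry: Registry,
    outcome: str,
    sex: str,
    covariates: Sequence[str],
    tau: float,
    grid: np.ndarray,
    n_nodes: int = 6,
    B: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapBand:
    """Pointwise (1 - level)/2 percentile envelopes of the tau-curve from B
    patient-level bootstrap refits.  Replicates whose refit fails are
    dropped and counted; more than 10% failures is an error."""
    if B < 2:
        raise ValidationError("B must be >= 2")
    covariates = tuple(covariates)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    eng = _CurveBootstrap(registry, outcome, sex, covariates, tau, n_nodes, grid)
    est = eng.fit(check_rank=True)
    reps, failed = [], 0
    for _ in range(B):
        try:
            reps.append(eng.fit(eng.resample(rng)))
        except (FitError, ValidationError):
            failed += 1
    if failed > 0.1 * B:
        raise FitError(f"{failed}/{B} bootstrap refits failed")
    reps = np.vstack(reps)
    alpha = (1.0 - level) / 2.0
    return BootstrapBand(
        tau=tau, grid=grid, estimate=est,
        lower=np.quantile(reps, alpha, axis=0),
        upper=np.quantile(reps, 1.0 - alpha, axis=0),
        level=level, B=B, seed=seed, n_failed=failed,
    )


def auc_difference(curve_a, curve_b, grid) -> float:
    """Trapezoid integral of (A - B) over the grid; antisymmetric in its
    arguments."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValidationError("grid needs at least 2 points")
    diff = np.asarray(curve_a, dtype=float) - np.asarray(curve_b, dtype=float)
    return float(np.trapezoid(diff, grid))


def auc_difference_test(
    registry_a: Registry,
    registry_b: Registry,
    outcome: str,
    sex: str,
    covariates: Sequence[str],
    tau: float,
    grid: np.ndarray,
    n_nodes: int = 6,
    B: int = 999,
    level: float = 0.95,
    seed: int = 0,
) -> TestResult:
    """Two-sided bootstrap test of zero AUC difference between the
    tau-curves of two registries.

    Both registries are resampled independently B times; the p-value is
    obtained from the bootstrap distribution of the statistic recentered at
    the observed value: p = (1 + #{|d*_b - d| >= |d|}) / (B + 1).
    """
    covariates = tuple(covariates)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    eng_a = _CurveBootstrap(registry_a, outcome, sex, covariates, tau, n_nodes, grid)
    eng_b = _CurveBootstrap(registry_b, outcome, sex, covariates, tau, n_nodes, grid)
    d_obs = auc_difference(eng_a.fit(check_rank=True), eng_b.fit(check_rank=True), grid)
    reps, failed = [], 0
    for _ in range(B):
        try:
            da = eng_a.fit(eng_a.resample(rng))
            db = eng_b.fit(eng_b.resample(rng))
            reps.append(auc_difference(da, db, grid))
        except (FitError, ValidationError):
            failed += 1
    if failed > 0.1 * B:
        raise FitError(f"{failed}/{B} bootstrap replicates failed")
    reps = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    ci = (float(np.quantile(reps, alpha)), float(np.quantile(reps, 1 - alpha)))
    centered = reps - d_obs  # null distribution of the statistic
    p = (1.0 + np.sum(np.abs(centered) >= abs(d_obs))) / (len(reps) + 1.0)
    return TestResult(
        label=f"auc_difference tau={tau}",
        statistic=d_obs, ci=ci, p_value=float(p),
        B=B, seed=seed, n=registry_a.n_records + registry_b.n_records,
    )


def chart_correlation(
    chart_a: PercentileChart,
    chart_b: PercentileChart,
    taus: Sequence[float] | None = None,
    grid: dict[str, np.ndarray] | None = None,
    n_grid: int = 50,
) -> float:
    """Pearson correlation of two charts' values over a tau × covariate
    lattice (default: the common taus × 50 equally spaced points over the
    overlap of the training ranges)."""
    if chart_a.outcome != chart_b.outcome or chart_a.covariates != chart_b.covariates:
        raise ValidationError("charts must share outcome and covariates")
    if grid is None:
        grid = {}
        for cov in chart_a.covariates:
            lo = max(chart_a.training_range(cov)[0], chart_b.training_range(cov)[0])
            hi = min(chart_a.training_range(cov)[1], chart_b.training_range(cov)[1])
            if not lo < hi:
                raise ValidationError(f"no overlapping training range for {cov}")
            grid[cov] = np.linspace(lo, hi, n_grid)
    if taus is not None:
        taus = np.asarray(taus, dtype=float)
        sel_a = np.isin(np.round(chart_a.taus, 10), np.round(taus, 10))
        sel_b = np.isin(np.round(chart_b.taus, 10), np.round(taus, 10))
    else:
        sel_a = np.isin(np.round(chart_a.taus, 10), np.round(chart_b.taus, 10))
        sel_b = np.isin(np.round(chart_b.taus, 10), np.round(chart_a.taus, 10))
    va = chart_a.curve_values(grid)[sel_a].ravel()
    vb = chart_b.curve_values(grid)[sel_b].ravel()
    tol = 1e-12 * max(1.0, abs(float(np.mean(va))), abs(float(np.mean(vb))))
    if np.std(va) < tol or np.std(vb) < tol:
        raise ValidationError("chart constant over the lattice; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def group_median_percentile(
    ranks: pd.DataFrame,
    B: int = 999,
    alpha: float = 0.05,
    m_comparisons: int | None = None,
    seed: int = 0,
) -> list[TestResult]:
    """Per (group, age class): median percentile rank with a bootstrap CI at
    Bonferroni-adjusted level 1 - alpha/m; flagged when the expected median
    (50) lies outside the CI.

    ``ranks`` columns: ``percentile_rank``, ``group``, ``age_class``.
    """
    required = {"percentile_rank", "group", "age_class"}
    if not required <= set(ranks.columns):
        raise ValidationError(f"ranks frame needs columns {sorted(required)}")
    cells = ranks.groupby(["group", "age_class"], sort=True, observed=True)
    m = m_comparisons if m_comparisons is not None else len(cells)
    level = 1.0 - alpha / m
    tail = (1.0 - level) / 2.0
    rng = np.random.default_rng(seed)
    results = []
    for (group, klass), cell in cells:
        x = cell["percentile_rank"].values
        if len(x) == 0:
            warnings.warn(f"empty cell ({group}, {klass}); skipped", stacklevel=2)
            continue
        med = float(np.median(x))
        boots = np.median(
            x[rng.integers(0, len(x), size=(B, len(x)))], axis=1
        )
        ci = (float(np.quantile(boots, tail)), float(np.quantile(boots, 1 - tail)))
        results.append(
            TestResult(
                label=f"{group}/{klass}",
                statistic=med, ci=ci, B=B, seed=seed,
                adjustment=f"bonferroni({m})",
                flagged=not (ci[0] <= 50.0 <= ci[1]),
                n=len(x),
            )
        )
    return results


def rank_compare_groups(ranks_a, ranks_b) -> float:
    """Two-sided Mann–Whitney–Wilcoxon p-value comparing two groups'
    percentile-rank distributions."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
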