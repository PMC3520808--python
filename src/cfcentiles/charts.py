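"""Quantile-regression percentile charts on cubic B-spline bases.

The chart machinery: a cubic B-spline basis in age (and optionally
height), one linear-programming quantile fit per percentile level tau,
the family of 1–99% curves per sex, evaluation on a covariate grid, and
the inverse lookup that ranks an individual measurement against the
chart.  Fitted quantile curves of different levels may cross in finite
samples; before rank lookup the 99 values at each covariate point are
monotonically rearranged (sorted), which restores a well-defined inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog

from .registry import Registry, ValidationError

DEFAULT_TAUS = tuple(np.round(np.arange(1, 100) / 100.0, 2))

#: age windows of the published analyses, per outcome (closed intervals)
AGE_WINDOWS = {"fev1": (6.0, 40.0), "bmi": (0.0, 40.0)}


class DomainError(ValueError):
    """Covariate outside the chart's training range (no extrapolation)."""


class FitError(RuntimeError):
    """The quantile fit could not be computed."""


# ---------------------------------------------------------------------------
# B-spline basis


@dataclass
class SplineSpec:
    """Cubic B-spline basis specification for one covariate.

    ``n_nodes`` counts the distinct knots including the two boundary knots
    (placed at the training data min/max); the ``n_nodes - 2`` interior
    knots sit at equally spaced quantiles of the covariate.  Basis
    dimension is therefore ``n_interior_knots + degree + 1``
    (8 for the default 6 nodes).
    """

    degree: int = 3
    n_nodes: int = 6
    knots: np.ndarray | None = None  # full knot vector incl. repeats, set by fit

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2 (the boundary knots)")
        if self.knots is not None:
            self.knots = np.asarray(self.knots, dtype=float)
            if np.any(np.diff(self.knots) < 0):
                raise ValidationError("knots must be nondecreasing")

    @property
    def is_fitted(self) -> bool:
        return self.knots is not None

    @property
    def dimension(self) -> int:
        if not self.is_fitted:
            raise FitError("spline knots not set; call fit_knots first")
        return len(self.knots) - self.degree - 1

    @property
    def boundary(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def fit_knots(self, x: np.ndarray) -> "SplineSpec":
        """Place boundary knots at min/max of x and interior knots at
        equally spaced quantiles; returns self."""
        x = np.asarray(x, dtype=float)
        qs = np.linspace(0, 1, self.n_nodes)
        nodes = np.quantile(x, qs)
        # collapse accidental duplicates (heavily tied data)
        nodes = np.unique(nodes)
        d = self.degree
        self.knots = np.concatenate(
            [np.repeat(nodes[0], d + 1), nodes[1:-1], np.repeat(nodes[-1], d + 1)]
        )
        return self

    def design_matrix(self, x: np.ndarray, extrapolate: bool = False) -> sparse.csr_matrix:
        """Sparse basis matrix, one row per value of x."""
        if not self.is_fitted:
            raise FitError("spline knots not set; call fit_knots first")
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        if not extrapolate and (np.any(x < lo) or np.any(x > hi)):
            raise DomainError(
                f"covariate values outside training range [{lo:.6g}, {hi:.6g}]"
            )
        xc = np.clip(x, lo, hi) if not extrapolate else x
        return BSpline.design_matrix(
            xc, self.knots, self.degree, extrapolate=extrapolate
        ).tocsr()


def bspline_basis(spec: SplineSpec, x: float) -> np.ndarray:
    """Basis vector at a single point (Cox–de Boor values; nonnegative,
    summing to one inside the boundary)."""
    return np.asarray(spec.design_matrix(np.atleast_1d(x)).todense()).ravel()


# ---------------------------------------------------------------------------
# pinball loss and the LP fit


def pinball_loss(tau: float, residual) -> np.ndarray | float:
    """Check loss r * (tau - 1{r < 0})."""
    if not 0 < tau < 1:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    r = np.asarray(residual, dtype=float)
    out = r * (tau - (r < 0))
    return float(out) if out.ndim == 0 else out


def fit_quantile(design, y: np.ndarray, tau: float) -> np.ndarray:
    """Minimize total pinball loss over coefficients: linear program.

    The primal program is min over (beta, u, v) of tau·1'u + (1-tau)·1'v
    subject to X beta + u - v = y, u, v >= 0.  For speed the equivalent
    dual — max y'd subject to X'd = 0, d in [tau-1, tau] — is solved with
    HiGHS (it has only p equality constraints instead of n), and the
    optimal beta is recovered as the negated equality-constraint marginals;
    strong duality makes the achieved losses identical.  Minimizers may be
    non-unique; callers should compare achieved loss, not raw coefficients.
    """
    if not 0 < tau < 1:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    X = sparse.csr_matrix(design) if not sparse.issparse(design) else design.tocsr()
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValidationError(f"design has {n} rows but y has {len(y)}")
    if n < p:
        raise FitError(f"n={n} observations < design dimension p={p}")
    if np.linalg.matrix_rank(X.toarray()) < p:
        raise FitError(
            f"rank-deficient design (p={p}); use fewer spline nodes or more data"
        )
    res = linprog(
        -y,
        A_eq=X.T.tocsc(),
        b_eq=np.zeros(p),
        bounds=np.column_stack(
            [np.full(n, tau - 1.0), np.full(n, tau)]
        ),
        method="highs",
    )
    if not res.success or res.eqlin is None:
        raise FitError(f"quantile LP failed: {res.message}")
    return -np.asarray(res.eqlin.marginals, dtype=float)


# ---------------------------------------------------------------------------
# charts


@dataclass
class QuantileModel:
    """A single fitted conditional quantile curve."""

    tau: float
    sex: str
    outcome: str
    covariates: tuple[str, ...]
    coef: np.ndarray

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)


def _build_design(
    specs: dict[str, SplineSpec],
    covariates: Sequence[str],
    values: dict[str, np.ndarray],
    extrapolate: bool = False,
) -> sparse.csr_matrix:
    """Additive design: full basis of the first covariate (its partition of
    unity supplies the intercept) plus the remaining bases with their first
    column dropped to avoid collinearity."""
    blocks = []
    for i, cov in enumerate(covariates):
        B = specs[cov].design_matrix(values[cov], extrapolate=extrapolate)
        blocks.append(B if i == 0 else B[:, 1:])
    return sparse.hstack(blocks, format="csr")


@dataclass
class PercentileChart:
    """A family of fitted quantile curves (one per tau) for one outcome,
    sex and covariate set, sharing the spline specification."""

    outcome: str
    sex: str
    covariates: tuple[str, ...]
    specs: dict[str, SplineSpec]
    models: list[QuantileModel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        taus = [m.tau for m in self.models]
        if np.any(np.diff(taus) <= 0):
            raise ValidationError("model taus must be strictly increasing")

    @property
    def taus(self) -> np.ndarray:
        return np.array([m.tau for m in self.models])

    def training_range(self, cov: str) -> tuple[float, float]:
        return self.specs[cov].boundary

    def _check_point(self, values: dict[str, float], extrapolate: bool) -> None:
        if extrapolate:
            return
        for cov in self.covariates:
            lo, hi = self.training_range(cov)
            v = values[cov]
            if not lo <= v <= hi:
                raise DomainError(
                    f"{cov}={v} outside training range [{lo:.6g}, {hi:.6g}]; "
                    "pass extrapolate=True to evaluate the polynomial tails"
                )

    def evaluate(self, tau: float, extrapolate: bool = False, **values: float) -> float:
        """Fitted value of the tau-curve at a covariate point."""
        idx = np.flatnonzero(np.isclose(self.taus, tau))
        if idx.size == 0:
            raise ValidationError(f"tau={tau} not in chart grid")
        self._check_point(values, extrapolate)
        arrs = {c: np.atleast_1d(float(values[c])) for c in self.covariates}
        X = _build_design(self.specs, self.covariates, arrs, extrapolate)
        return float(np.asarray(X @ self.models[idx[0]].coef)[0])

    def curve_values(
        self, grid: dict[str, np.ndarray], rearranged: bool = False,
        extrapolate: bool = False,
    ) -> np.ndarray:
        """(n_taus, n_points) matrix of curve values over a covariate grid;
        optionally monotonically rearranged across taus at each point."""
        arrs = {c: np.asarray(grid[c], dtype=float) for c in self.covariates}
        X = _build_design(self.specs, self.covariates, arrs, extrapolate)
        vals = np.vstack([X @ m.coef for m in self.models])
        return np.sort(vals, axis=0) if rearranged else vals

    def percentile_rank(
        self, observed: float, extrapolate: bool = False, **values: float
    ) -> float:
        """Percentile rank (1–99 scale) of an observed value at a covariate
        point: the largest tau whose (rearranged) curve lies at or below the
        observation, linearly interpolated between adjacent curves and
        clamped to [1, 99]."""
        self._check_point(values, extrapolate)
        arrs = {c: np.atleast_1d(float(values[c])) for c in self.covariates}
        curves = self.curve_values(arrs, rearranged=True, extrapolate=extrapolate)[:, 0]
        pct = self.taus * 100.0
        return float(np.interp(observed, curves, pct, left=pct[0], right=pct[-1]))

    def rank_records(self, registry: Registry, extrapolate: bool = False) -> pd.Series:
        """Percentile ranks for every record of a (filtered) registry of the
        chart's sex; vectorised."""
        frame = registry.frame[registry.frame["sex"] == self.sex]
        colmap = {"age": "age_years", "height": "height_cm"}
        grid = {c: frame[colmap[c]].values for c in self.covariates}
        if self.outcome == "fev1":
            obs = frame["fev1_l"].values
        else:
            obs = (frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2).values
        curves = self.curve_values(grid, rearranged=True, extrapolate=extrapolate)
        pct = self.taus * 100.0
        ranks = np.empty(len(frame))
        for j in range(curves.shape[1]):
            ranks[j] = np.interp(obs[j], curves[:, j], pct, left=pct[0], right=pct[-1])
        return pd.Series(ranks, index=frame.index, name="percentile_rank")

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "sex": self.sex,
            "covariates": list(self.covariates),
            "specs": {
                c: {
                    "degree": s.degree,
                    "n_nodes": s.n_nodes,
                    "knots": s.knots.tolist(),
                }
                for c, s in self.specs.items()
            },
            "taus": self.taus.tolist(),
            "coefficients": [m.coef.tolist() for m in self.models],
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            from .io import atomic_write_text

            atomic_write_text(Path(path), text)
        return text

    @classmethod
    def from_json(cls, source) -> "PercentileChart":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        specs = {
            c: SplineSpec(degree=d["degree"], n_nodes=d["n_nodes"], knots=np.array(d["knots"]))
            for c, d in payload["specs"].items()
        }
        covs = tuple(payload["covariates"])
        models = [
            QuantileModel(tau=t, sex=payload["sex"], outcome=payload["outcome"],
                          covariates=covs, coef=np.array(co))
            for t, co in zip(payload["taus"], payload["coefficients"])
        ]
        return cls(
            outcome=payload["outcome"], sex=payload["sex"], covariates=covs,
            specs=specs, models=models, metadata=payload.get("metadata", {}),
        )

    def curves_frame(self, grid: dict[str, np.ndarray]) -> pd.DataFrame:
        """Long-format table (sex, outcome, tau, covariates…, value) over a
        grid, for plotting and interchange."""
        vals = self.curve_values(grid)
        rows = []
        for i, tau in enumerate(self.taus):
            df = pd.DataFrame({c: np.asarray(grid[c]) for c in self.covariates})
            df.insert(0, "sex", self.sex)
            df.insert(1, "outcome", self.outcome)
            df.insert(2, "tau", tau)
            df["value"] = vals[i]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# registry-level operations


def filter_registry(registry: Registry, outcome: str) -> Registry:
    """Apply the published analysis filters: post-transplant measurements
    removed for all analyses; FEV1 analyses keep ages [6, 40] with an FEV1
    value present; BMI analyses keep ages [0, 40] with weight present."""
    if outcome not in AGE_WINDOWS:
        raise ValidationError(f"outcome must be 'fev1' or 'bmi', got {outcome!r}")
    lo, hi = AGE_WINDOWS[outcome]
    f = registry.frame
    keep = ~f["transplanted"].astype(bool)
    keep &= (f["age_years"] >= lo) & (f["age_years"] <= hi)
    if outcome == "fev1":
        keep &= f["fev1_l"].notna()
    else:
        keep &= f["weight_kg"].notna()
    out = registry.with_frame(
        f[keep],
        extra_filter=f"{outcome}: no transplant, age in [{lo:g}, {hi:g}]",
    )
    if out.n_records == 0:
        import warnings

        warnings.warn(f"registry empty after {outcome} filter", stacklevel=2)
    return out


def fit_chart(
    registry: Registry,
    outcome: str,
    sex: str,
    covariates: Sequence[str] = ("age",),
    taus: Sequence[float] = DEFAULT_TAUS,
    specs: dict[str, SplineSpec] | None = None,
) -> PercentileChart:
    """Fit the family of percentile curves for one sex.

    The registry should already be filtered (see :func:`filter_registry`).
    The age+height model is additive: spline in age plus spline in height
    with a shared intercept carried by the age basis.
    """
    covariates = tuple(covariates)
    frame = registry.frame[registry.frame["sex"] == sex]
    if frame.empty:
        raise FitError(f"no records for sex {sex!r}")
    colmap = {"age": "age_years", "height": "height_cm"}
    values = {c: frame[colmap[c]].values.astype(float) for c in covariates}
    if outcome == "fev1":
        y = frame["fev1_l"].values.astype(float)
    elif outcome == "bmi":
        y = (frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2).values
    else:
        raise ValidationError(f"outcome must be 'fev1' or 'bmi', got {outcome!r}")
    if np.any(np.isnan(y)):
        raise FitError(
            f"{np.isnan(y).sum()} missing {outcome} values; filter the registry first"
        )

    if specs is None:
        specs = {c: SplineSpec() for c in covariates}
    for c in covariates:
        if not specs[c].is_fitted:
            specs[c].fit_knots(values[c])
    X = _build_design(specs, covariates, values)
    if len(y) < X.shape[1]:
        raise FitError(
            f"{len(y)} records < design dimension {X.shape[1]}; "
            "reduce n_nodes or provide more data"
        )
    models = []
    for tau in taus:
        coef = fit_quantile(X, y, float(tau))
        models.append(
            QuantileModel(tau=float(tau), sex=sex, outcome=outcome,
                          covariates=covariates, coef=coef)
        )
    corrected = (frame["measurement_type"] == "corrected").any()
    meta = {
        "n": int(len(y)),
        "filters": list(registry.filters_applied),
        "correction_applied": bool(corrected),
        "knot_rule": "boundary at data min/max, interior at equally spaced quantiles",
    }
    return PercentileChart(
        outcome=outcome, sex=sex, covariates=covariates,
        specs=specs, models=models, metadata=meta,
    )


def percentile_rank(
    chart: PercentileChart, observed: float, **values: float
) -> float:
    """Module-level convenience wrapper around chart.percentile_rank."""
    return chart.percentile_rank(observed, **values)
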