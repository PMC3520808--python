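"""Referencing a measurement against a healthy population.

Two classical devices:

* **Percent predicted FEV1** — a sex/age-stratified linear prediction
  equation (Knudson-style) gives the FEV1 expected for a healthy person of
  the same sex, age and height; the observation is expressed as
  ``100 * observed / predicted``.
* **LMS z-scores** — an age/sex-indexed table of skewness (L), median (M)
  and coefficient of variation (S) defines ``z = ((x/M)^L - 1)/(L*S)``
  (``ln(x/M)/S`` when L = 0), the standard construction behind modern
  growth standards such as WHO 2007.

Both engines are table-driven and pluggable: the bundled CSVs are
clearly-labelled synthetic stand-ins with the same schema as the published
references, so a published coefficient table can be substituted verbatim.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import SEXES, ValidationError


class DomainError(ValueError):
    """Input outside the declared domain of a reference table."""


def _read_table_csv(source) -> pd.DataFrame:
    """Read a coefficient CSV, skipping '#' header comment lines."""
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, comment="#")
    return pd.read_csv(io.StringIO(source.read_text() if hasattr(source, "read_text") else source), comment="#")


@dataclass(frozen=True)
class PredictionEquationSet:
    """Sex/age-stratified linear FEV1 prediction equations.

    Each stratum ``(sex, [age_lo, age_hi))`` carries an intercept, an age
    coefficient (L/year) and a height coefficient (L/cm).  Strata are
    half-open on the right except the last stratum of each sex, which is
    closed, so the declared age range is covered without overlap.  Values
    may jump at stratum boundaries; the discontinuity is inherent to this
    family of references and is not smoothed.
    """

    table: pd.DataFrame

    REQUIRED = ("sex", "age_lo", "age_hi", "intercept", "age_coef", "height_coef")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"prediction table missing columns: {missing}")
        for sex, grp in self.table.groupby("sex"):
            if sex not in SEXES:
                raise ValidationError(f"unknown sex code {sex!r} in prediction table")
            g = grp.sort_values("age_lo")
            if not np.all(g["age_lo"].values[1:] >= g["age_hi"].values[:-1]):
                raise ValidationError(f"overlapping age strata for sex {sex}")

    @classmethod
    def from_csv(cls, path) -> "PredictionEquationSet":
        return cls(_read_table_csv(path))

    def age_range(self, sex: str) -> tuple[float, float]:
        g = self.table[self.table["sex"] == sex]
        return float(g["age_lo"].min()), float(g["age_hi"].max())

    def stratum(self, sex: str, age: float) -> pd.Series:
        g = self.table[self.table["sex"] == sex].sort_values("age_lo")
        if g.empty:
            raise DomainError(f"no strata for sex {sex!r}")
        last = g.index[-1]
        for idx, row in g.iterrows():
            hi_ok = age <= row["age_hi"] if idx == last else age < row["age_hi"]
            if row["age_lo"] <= age and hi_ok:
                return row
        lo, hi = self.age_range(sex)
        raise DomainError(
            f"age {age} outside supported range [{lo}, {hi}] for sex {sex}"
        )


def predicted_fev1(
    equations: PredictionEquationSet, sex: str, age: float, height: float
) -> float:
    """Healthy-reference FEV1 (liters) for the given sex, age and height."""
    if not 50 <= height <= 220:
        raise DomainError(f"height {height} cm outside plausible range [50, 220]")
    row = equations.stratum(sex, age)
    value = row["intercept"] + row["age_coef"] * age + row["height_coef"] * height
    if value <= 0:
        raise DomainError(
            f"prediction nonpositive ({value:.3f} L) at sex={sex}, age={age}, "
            f"height={height}; outside the table's sensible domain"
        )
    return float(value)


def percent_predicted(observed: float, predicted: float) -> float:
    """``100 * observed / predicted``; scale-equivariant."""
    if predicted <= 0:
        raise DomainError(f"predicted must be > 0, got {predicted}")
    if observed < 0:
        raise DomainError(f"observed must be >= 0, got {observed}")
    # ratio first: observed == predicted yields exactly 100.0
    return 100.0 * (observed / predicted)


def lms_zscore(x, L, M, S):
    """z-score of x under an LMS law: ((x/M)^L - 1)/(L*S), ln(x/M)/S at L=0."""
    x, L, M, S = (np.asarray(v, dtype=float) for v in (x, L, M, S))
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise DomainError("x, M and S must all be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            L == 0,
            np.log(x / M) / S,
            (np.power(x / M, L) - 1.0) / (np.where(L == 0, 1.0, L) * S),
        )
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class LMSReference:
    """Sex-indexed (age, L, M, S) rows; linear interpolation in age, no
    extrapolation beyond the tabulated range."""

    table: pd.DataFrame

    REQUIRED = ("sex", "age_years", "L", "M", "S")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"LMS table missing columns: {missing}")
        for sex, grp in self.table.groupby("sex"):
            ages = grp["age_years"].values
            if not np.all(np.diff(ages) > 0):
                raise ValidationError(f"ages not strictly increasing for sex {sex}")
            if np.any(grp["M"].values <= 0) or np.any(grp["S"].values <= 0):
                raise ValidationError("M and S must be > 0 throughout")

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(_read_table_csv(path))

    def age_range(self, sex: str) -> tuple[float, float]:
        g = self.table[self.table["sex"] == sex]
        return float(g["age_years"].min()), float(g["age_years"].max())


def lookup_lms(reference: LMSReference, sex: str, age: float) -> tuple[float, float, float]:
    """(L, M, S) at the given age, linearly interpolated between rows."""
    g = reference.table[reference.table["sex"] == sex]
    if g.empty:
        raise DomainError(f"no LMS rows for sex {sex!r}")
    lo, hi = reference.age_range(sex)
    if not lo <= age <= hi:
        raise DomainError(f"age {age} outside LMS table range [{lo}, {hi}]")
    ages = g["age_years"].values
    return tuple(
        float(np.interp(age, ages, g[c].values)) for c in ("L", "M", "S")
    )


def bmi_zscore(reference: LMSReference, sex: str, age: float, bmi: float) -> float:
    """BMI z-score against the reference at (sex, age)."""
    L, M, S = lookup_lms(reference, sex, age)
    return float(lms_zscore(bmi, L, M, S))


def _data_path(name: str):
    return resources.files("cfcentiles.data").joinpath(name)


def load_default_prediction_equations() -> PredictionEquationSet:
    """The bundled synthetic Knudson-style FEV1 equation table."""
    with resources.as_file(_data_path("fev1_prediction_synthetic.csv")) as p:
        return PredictionEquationSet.from_csv(p)


def load_default_bmi_reference() -> LMSReference:
    """The bundled synthetic WHO-2007-style BMI LMS table."""
    with resources.as_file(_data_path("bmi_lms_synthetic.csv")) as p:
        return LMSReference.from_csv(p)
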