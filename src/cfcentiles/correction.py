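"""Best-annual-value correction for FEV1.

Some registries report the year's highest ("best") FEV1 rather than an
arbitrary visit; charts built from best values overestimate the reference
curves for patients assessed from unselected measurements.  Using
visit-level longitudinal data, the sex × age-band mean excess of the best
annual value over an unselected value of the same year is estimated, and
subtracted from reported best values before fitting.

"Unselected value of the same year" is operationalised as the expectation
over a uniformly drawn visit, so a patient-year's excess is
``max(visits) - mean(visits)``; a seeded alternative draws one random
visit instead (``method='random'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .registry import PatientRecord, Registry, ValidationError

#: default sex-shared age bands over the FEV1 analysis window, [lo, hi)
#: except the last band which is closed
DEFAULT_AGE_BANDS = ((6.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, 30.0), (30.0, 40.0))

FLOOR_L = 0.05  # corrected FEV1 floored at this small positive volume


class CorrectionError(ValueError):
    """The correction table cannot cover the requested record."""


@dataclass
class CorrectionTable:
    """Rows of (sex, age band, delta, n_patient_years) where delta (liters)
    is the mean best-minus-unselected difference in the band."""

    table: pd.DataFrame  # columns sex, age_lo, age_hi, delta, n_patient_years

    REQUIRED = ("sex", "age_lo", "age_hi", "delta", "n_patient_years")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"correction table missing columns: {missing}")
        if (self.table["delta"].dropna() < 0).any():
            warnings.warn(
                "negative best-minus-unselected delta in correction table",
                stacklevel=2,
            )

    def delta(self, sex: str, age: float) -> float:
        g = self.table[self.table["sex"] == sex].sort_values("age_lo")
        last = g.index[-1] if len(g) else None
        for idx, row in g.iterrows():
            hi_ok = age <= row["age_hi"] if idx == last else age < row["age_hi"]
            if row["age_lo"] <= age and hi_ok:
                if pd.isna(row["delta"]):
                    raise CorrectionError(
                        f"band [{row['age_lo']}, {row['age_hi']}) for sex {sex} "
                        "has no eligible patient-years"
                    )
                return float(row["delta"])
        gaps = [(r["age_lo"], r["age_hi"]) for _, r in g.iterrows()]
        raise CorrectionError(
            f"no correction band covers sex={sex}, age={age}; bands: {gaps}"
        )

    def to_csv(self, path) -> None:
        from .io import atomic_write_text

        atomic_write_text(path, self.table.to_csv(index=False))

    @classmethod
    def from_csv(cls, path) -> "CorrectionTable":
        return cls(pd.read_csv(path))


def estimate_correction(
    longitudinal: pd.DataFrame | Registry,
    age_bands=DEFAULT_AGE_BANDS,
    method: str = "expectation",
    seed: int = 0,
) -> CorrectionTable:
    """Estimate the correction from visit-level data.

    ``longitudinal`` is a visit table (columns patient_id, year, sex,
    age_years, fev1_l, one row per visit) or a Registry carrying one.  Per
    patient-year with >= 2 visits the difference is ``max - mean`` of the
    visits (``method='expectation'``) or ``max`` minus one uniformly drawn
    visit (``method='random'``, seeded).  The band entry is the mean of the
    patient-year differences; empty bands are flagged missing (NaN delta).
    """
    if isinstance(longitudinal, Registry):
        longitudinal = longitudinal.longitudinal
    if longitudinal is None or longitudinal.empty:
        raise ValidationError("no longitudinal visit data available")
    if method not in ("expectation", "random"):
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)

    grp = longitudinal.groupby(["patient_id", "year", "sex"], sort=False)
    agg = grp["fev1_l"].agg(["max", "mean", "count"])
    age = grp["age_years"].first()
    multi = agg["count"] >= 2
    if method == "expectation":
        diff = agg["max"] - agg["mean"]
    else:
        picks = grp["fev1_l"].agg(
            lambda v: v.iloc[rng.integers(len(v))]
        )
        diff = agg["max"] - picks
    diff, age = diff[multi], age[multi]
    if diff.empty:
        raise ValidationError("no patient-year has >= 2 visits")

    rows = []
    last = len(age_bands) - 1
    for sex in ("M", "F"):
        in_sex = diff.index.get_level_values("sex") == sex
        for i, (lo, hi) in enumerate(age_bands):
            a = age[in_sex]
            mask = (a >= lo) & ((a <= hi) if i == last else (a < hi))
            d = diff[in_sex][mask.values]
            rows.append(
                {
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "delta": float(d.mean()) if len(d) else np.nan,
                    "n_patient_years": int(len(d)),
                }
            )
    return CorrectionTable(pd.DataFrame(rows))


def apply_correction(record: PatientRecord, table: CorrectionTable) -> PatientRecord:
    """Convert a best-annual record to an unselected-equivalent one.

    Best records have the band delta subtracted (floored at a small
    positive volume) and are relabelled ``corrected``; unselected records
    pass through unchanged.
    """
    if record.fev1_l is None or record.measurement_type != "best":
        return record
    delta = table.delta(record.sex, record.age_years)
    corrected = record.fev1_l - delta
    if corrected <= 0:
        warnings.warn(
            f"corrected FEV1 nonpositive for {record.patient_id}; "
            f"floored at {FLOOR_L} L",
            stacklevel=2,
        )
        corrected = FLOOR_L
    return replace(record, fev1_l=corrected, measurement_type="corrected")


def apply_correction_registry(registry: Registry, table: CorrectionTable) -> Registry:
    """Vectorised :func:`apply_correction` over a whole registry."""
    f = registry.frame.copy()
    is_best = (f["measurement_type"] == "best") & f["fev1_l"].notna()
    if is_best.any():
        deltas = np.array(
            [
                table.delta(s, a)
                for s, a in zip(f.loc[is_best, "sex"], f.loc[is_best, "age_years"])
            ]
        )
        corrected = f.loc[is_best, "fev1_l"].values - deltas
        n_floor = int((corrected <= 0).sum())
        if n_floor:
            warnings.warn(
                f"{n_floor} corrected FEV1 values nonpositive; floored at {FLOOR_L} L",
                stacklevel=2,
            )
        f.loc[is_best, "fev1_l"] = np.maximum(corrected, FLOOR_L)
        f.loc[is_best, "measurement_type"] = "corrected"
    return registry.with_frame(f, extra_filter="best-value correction applied")
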