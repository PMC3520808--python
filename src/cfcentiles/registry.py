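"""Patient-registry container and record-level validation.

A :class:`Registry` wraps a pandas DataFrame in a fixed column schema
(one row per patient-visit measurement) together with provenance text and
the list of filters already applied to it.  Multiple rows per
``(patient_id, year)`` are allowed — registries report annual measurements
but patients may appear across several calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: canonical column order of the registry table
COLUMNS = [
    "patient_id",
    "country",
    "year",
    "sex",
    "age_years",
    "height_cm",
    "weight_kg",
    "fev1_l",
    "measurement_type",
    "transplanted",
    "genotype_class",
]

SEXES = ("M", "F")
MEASUREMENT_TYPES = ("best", "unselected", "corrected")
GENOTYPE_CLASSES = ("F508del_hom", "other", "unknown")


class ValidationError(ValueError):
    """A record or table violates the registry schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient-visit measurement row.

    FEV1 may be absent (``None``) — BMI-only records, typically ages 0–6
    where spirometry is not feasible.  BMI is derived, never stored:
    ``weight_kg / (height_cm / 100) ** 2``.
    """

    patient_id: str
    country: str
    year: int
    sex: str
    age_years: float
    height_cm: float
    weight_kg: float | None = None
    fev1_l: float | None = None
    measurement_type: str = "unselected"
    transplanted: bool = False
    genotype_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ValidationError(
                f"measurement_type must be one of {MEASUREMENT_TYPES}, "
                f"got {self.measurement_type!r}"
            )
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValidationError(
                f"genotype_class must be one of {GENOTYPE_CLASSES}, "
                f"got {self.genotype_class!r}"
            )
        if self.age_years < 0:
            raise ValidationError(f"age_years must be >= 0, got {self.age_years}")
        if not self.height_cm > 0:
            raise ValidationError(f"height_cm must be > 0, got {self.height_cm}")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ValidationError(f"weight_kg must be > 0, got {self.weight_kg}")
        if self.fev1_l is not None and not self.fev1_l > 0:
            raise ValidationError(f"fev1_l must be > 0, got {self.fev1_l}")

    @property
    def bmi(self) -> float | None:
        if self.weight_kg is None:
            return None
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass
class Registry:
    """An ordered collection of patient-visit records plus metadata."""

    frame: pd.DataFrame
    provenance: str = ""
    filters_applied: list[str] = field(default_factory=list)
    #: visit-level table (all within-year visits), populated by the simulator
    #: or by registries with systematic longitudinal collection
    longitudinal: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"registry frame missing columns: {missing}")
        # canonical columns first; unknown columns preserved but ignored
        extra = [c for c in self.frame.columns if c not in COLUMNS]
        self.frame = self.frame[COLUMNS + extra].reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Sequence[PatientRecord], provenance: str = ""
    ) -> "Registry":
        frame = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "country": r.country,
                    "year": r.year,
                    "sex": r.sex,
                    "age_years": r.age_years,
                    "height_cm": r.height_cm,
                    "weight_kg": np.nan if r.weight_kg is None else r.weight_kg,
                    "fev1_l": np.nan if r.fev1_l is None else r.fev1_l,
                    "measurement_type": r.measurement_type,
                    "transplanted": r.transplanted,
                    "genotype_class": r.genotype_class,
                }
                for r in records
            ],
            columns=COLUMNS,
        )
        return cls(frame=frame, provenance=provenance)

    def records(self) -> Iterator[PatientRecord]:
        for row in self.frame.itertuples(index=False):
            yield PatientRecord(
                patient_id=row.patient_id,
                country=row.country,
                year=int(row.year),
                sex=row.sex,
                age_years=float(row.age_years),
                height_cm=float(row.height_cm),
                weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                fev1_l=None if pd.isna(row.fev1_l) else float(row.fev1_l),
                measurement_type=row.measurement_type,
                transplanted=bool(row.transplanted),
                genotype_class=row.genotype_class,
            )

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def bmi(self) -> pd.Series:
        """BMI in kg/m² per record (NaN where weight is missing)."""
        return self.frame["weight_kg"] / (self.frame["height_cm"] / 100.0) ** 2

    def with_frame(self, frame: pd.DataFrame, extra_filter: str | None = None) -> "Registry":
        """Copy with a new frame, appending ``extra_filter`` to provenance."""
        filters = list(self.filters_applied)
        if extra_filter is not None:
            filters.append(extra_filter)
        reg = Registry(
            frame=frame.copy(),
            provenance=self.provenance,
            filters_applied=filters,
        )
        reg.longitudinal = self.longitudinal
        return reg

    @property
    def patient_indices(self) -> dict:
        """Row indices per patient id, cached (bootstrap resampling hot path)."""
        cache = getattr(self, "_patient_indices", None)
        if cache is None:
            cache = self.frame.groupby("patient_id", sort=False).indices
            object.__setattr__(self, "_patient_indices", cache)
        return cache

    def subset_patients(self, patient_ids: Sequence[str]) -> "Registry":
        """Rows for the given patient ids, repeated per occurrence (bootstrap)."""
        groups = self.patient_indices
        idx = np.concatenate([groups[p] for p in patient_ids])
        return self.with_frame(self.frame.iloc[idx])

    def __len__(self) -> int:
        return len(self.frame)
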