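"""Registry CSV dialect, atomic writes, configuration and summaries.

Registry CSV: comma-separated UTF-8 with a mandatory header and columns
``patient_id, country, year, sex, age_years, height_cm, weight_kg, fev1_l,
measurement_type, transplanted, genotype_class``.  ``fev1_l`` may be blank
(BMI-only records); ``transplanted`` is 0/1.  Unknown columns are
preserved on read but ignored by the analyses.  Row-level schema
violations are reported with their row numbers; more than 5% invalid rows
is fatal.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registry import (
    COLUMNS,
    GENOTYPE_CLASSES,
    MEASUREMENT_TYPES,
    SEXES,
    Registry,
    ValidationError,
)
from .reference import (
    DomainError,
    LMSReference,
    PredictionEquationSet,
    bmi_zscore,
)


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file in the target directory + rename, so partial
    writes never corrupt an existing artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_registry_csv(registry: Registry, path) -> None:
    atomic_write_text(Path(path), registry.frame.to_csv(index=False))


def read_registry_csv(path, max_invalid_fraction: float = 0.05) -> Registry:
    """Read and validate a registry CSV.

    Invalid rows (bad sex or measurement-type code, nonpositive height,
    negative age…) are dropped and reported with their 1-based data row
    numbers; exceeding ``max_invalid_fraction`` raises instead.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str, "country": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    errors: list[str] = []

    def flag(mask: pd.Series, message: str) -> None:
        for i in frame.index[mask]:
            errors.append(f"row {i + 1}: {message}")

    bad = pd.Series(False, index=frame.index)
    m = ~frame["sex"].isin(SEXES)
    flag(m, "invalid sex code")
    bad |= m
    m = ~frame["measurement_type"].isin(MEASUREMENT_TYPES)
    flag(m, "invalid measurement_type")
    bad |= m
    m = ~frame["genotype_class"].isin(GENOTYPE_CLASSES)
    flag(m, "invalid genotype_class")
    bad |= m
    m = ~(frame["height_cm"] > 0)
    flag(m, "nonpositive height_cm")
    bad |= m
    m = frame["age_years"] < 0
    flag(m, "negative age_years")
    bad |= m
    m = frame["weight_kg"].notna() & ~(frame["weight_kg"] > 0)
    flag(m, "nonpositive weight_kg")
    bad |= m
    m = frame["fev1_l"].notna() & ~(frame["fev1_l"] > 0)
    flag(m, "nonpositive fev1_l")
    bad |= m

    if bad.sum() > max_invalid_fraction * max(len(frame), 1):
        raise ValidationError(
            f"{path}: {bad.sum()}/{len(frame)} invalid rows; first errors: "
            + "; ".join(errors[:10])
        )
    if errors:
        warnings.warn(
            f"{path}: dropped {bad.sum()} invalid rows ({'; '.join(errors[:10])}"
            + ("; …" if len(errors) > 10 else ")"),
            stacklevel=2,
        )
    frame = frame[~bad]
    frame = frame.astype({"year": int, "transplanted": bool})
    reg = Registry(frame=frame, provenance=f"read from {path.name}")
    return reg


def predicted_fev1_column(
    frame: pd.DataFrame, equations: PredictionEquationSet
) -> pd.Series:
    """Vectorised healthy-reference FEV1 per row (NaN outside the table)."""
    pred = pd.Series(np.nan, index=frame.index)
    tab = equations.table
    for sex, g in tab.groupby("sex"):
        g = g.sort_values("age_lo")
        last_idx = g.index[-1]
        for idx, row in g.iterrows():
            hi_ok = (
                frame["age_years"] <= row["age_hi"]
                if idx == last_idx
                else frame["age_years"] < row["age_hi"]
            )
            mask = (
                (frame["sex"] == sex)
                & (frame["age_years"] >= row["age_lo"])
                & hi_ok
            )
            pred[mask] = (
                row["intercept"]
                + row["age_coef"] * frame.loc[mask, "age_years"]
                + row["height_coef"] * frame.loc[mask, "height_cm"]
            )
    return pred.where(pred > 0)


def summarize_registry(
    registry: Registry,
    equations: PredictionEquationSet | None = None,
    lms: LMSReference | None = None,
    by: str = "country",
) -> pd.DataFrame:
    """Demographic summary per group: patients, measurements, % female,
    FEV1 percent predicted (mean ± SD), BMI z-score (mean ± SD), % adults
    (> 20 y)."""
    if registry.n_records == 0:
        raise ValidationError("cannot summarize an empty registry")
    f = registry.frame.copy()
    f["bmi"] = f["weight_kg"] / (f["height_cm"] / 100.0) ** 2
    if equations is not None:
        pred = predicted_fev1_column(f, equations)
        f["fev1pp"] = 100.0 * f["fev1_l"] / pred
    else:
        f["fev1pp"] = np.nan
    if lms is not None:
        zs = np.full(len(f), np.nan)
        for i, (sex, age, bmi) in enumerate(
            zip(f["sex"], f["age_years"], f["bmi"])
        ):
            if pd.isna(bmi):
                continue
            try:
                zs[i] = bmi_zscore(lms, sex, age, bmi)
            except DomainError:
                pass
        f["bmi_z"] = zs
    else:
        f["bmi_z"] = np.nan

    rows = []
    for group, g in f.groupby(by):
        patients = g["patient_id"].nunique()
        adults = g[g["age_years"] > 20]["patient_id"].nunique()
        rows.append(
            {
                by: group,
                "n_patients": patients,
                "n_measurements": len(g),
                "pct_female": 100.0 * (g["sex"] == "F").mean(),
                "fev1pp_mean": g["fev1pp"].mean(),
                "fev1pp_sd": g["fev1pp"].std(),
                "bmi_z_mean": g["bmi_z"].mean(),
                "bmi_z_sd": g["bmi_z"].std(),
                "pct_adults": 100.0 * adults / patients,
            }
        )
    return pd.DataFrame(rows)


def load_sim_config(path) -> "SimConfig":
    """Build a :class:`~cfcentiles.simulate.SimConfig` from a YAML file;
    unknown keys are rejected, country entries become CountrySpec."""
    from .simulate import CountrySpec, SimConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "country_labels" in raw:
        raw["country_labels"] = tuple(
            CountrySpec(**c) for c in raw["country_labels"]
        )
    for key in ("age_range", "years"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
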