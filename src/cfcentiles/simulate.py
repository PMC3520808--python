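"""Seeded synthetic CF-registry generator with closed-form ground truth.

The generator emulates the statistical structure of a multinational CF
patient registry: two sexes, ages 0–40, FEV1 measured from age 6 with a
rise to a sex-specific peak (≈3 L at 18 y in males, ≈2.3 L at 16 y in
females) followed by a roughly linear decline, FEV1 increasing with
height (≈0.25 L per extra 10 cm near the peak), BMI drawn from
disease-specific LMS curves that fall below a healthy standard after
childhood, repeated within-year visits (so that "best annual value"
reporting induces a selection bias), and country groups with configurable
sampling weights and reporting conventions.

Every conditional quantile of the generated data has a closed form
(:func:`true_quantile`), which is what makes parameter-recovery and
coverage tests of the fitting machinery possible.

Model
-----
FEV1 for a single visit is log-normal around a median surface

    m(sex, age, height) = f_age(sex, age) * (1 + beta * (height - h_med(age)))

with ``log FEV1 ~ N(log m, sigma^2)``.  Within a patient-year the k visits
share a patient-year effect: ``log FEV1 = log m + sigma_b * Z + sigma_w * eps``
with ``sigma_b^2 + sigma_w^2 = sigma^2``, so the marginal law of any single
visit is unchanged while the best-of-k value exceeds an unselected visit
by a realistic 0.1–0.2 L.  BMI follows the configured LMS curves exactly:
``BMI = M(age) * (1 + L*S*Z)**(1/L)`` with ``Z ~ N(0, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registry import COLUMNS, Registry, ValidationError


@dataclass(frozen=True)
class CountrySpec:
    """A simulated country: comparison-group tag, sampling weight and
    whether its registry reports the best annual FEV1 or an unselected one."""

    name: str
    group: str
    weight: float
    reports_best: bool


def _default_countries() -> tuple[CountrySpec, ...]:
    # France and Germany report unselected values; the smaller high-coverage
    # and low-coverage groups report best annual values.
    return (
        CountrySpec("France", "FR", 0.30, False),
        CountrySpec("Germany", "DE", 0.30, False),
        CountrySpec("Denmark", "high_coverage", 0.10, True),
        CountrySpec("Israel", "high_coverage", 0.12, True),
        CountrySpec("Italy", "low_coverage", 0.10, True),
        CountrySpec("Sweden", "low_coverage", 0.08, True),
    )


def _default_bmi_lms() -> dict[str, list[tuple[float, float, float, float]]]:
    # (age, L, M, S): BMI median dips after infancy, rebounds, and stays
    # below a healthy adult plateau — the post-childhood deficit typical of CF.
    male = [
        (0.0, -0.5, 13.4, 0.09),
        (1.0, -0.5, 17.0, 0.09),
        (4.0, -0.5, 15.8, 0.09),
        (8.0, -0.5, 16.2, 0.10),
        (12.0, -0.5, 17.5, 0.11),
        (16.0, -0.5, 19.0, 0.11),
        (20.0, -0.5, 20.5, 0.11),
        (30.0, -0.5, 21.0, 0.11),
        (40.0, -0.5, 21.2, 0.11),
    ]
    female = [
        (0.0, -0.5, 13.3, 0.09),
        (1.0, -0.5, 16.8, 0.09),
        (4.0, -0.5, 15.6, 0.09),
        (8.0, -0.5, 16.0, 0.10),
        (12.0, -0.5, 17.3, 0.11),
        (16.0, -0.5, 18.6, 0.11),
        (20.0, -0.5, 19.5, 0.11),
        (30.0, -0.5, 19.8, 0.11),
        (40.0, -0.5, 20.0, 0.11),
    ]
    return {"M": male, "F": female}


@dataclass
class SimConfig:
    """Parameters of the synthetic registry.

    Defaults are calibrated to the published European CF registry
    landmarks: median FEV1 ≈ 1 L at age 6 for both sexes, rising to 3 L at
    18 y (males) and 2.3 L at 16 y (females) and declining thereafter;
    log-scale SD 0.32 reproduces an interquartile range of roughly
    2.4–3.7 L at the male peak; the height effect is ≈0.25–0.3 L per
    10 cm near the peak.
    """

    n_patients_per_sex: int = 1000
    age_range: tuple[float, float] = (0.0, 40.0)
    #: first spirometry age in years (FEV1 absent below this)
    fev1_min_age: float = 6.0
    peak_age: dict[str, float] = field(default_factory=lambda: {"M": 18.0, "F": 16.0})
    peak_median_fev1: dict[str, float] = field(
        default_factory=lambda: {"M": 3.0, "F": 2.3}
    )
    #: median FEV1 at fev1_min_age, both sexes (liters)
    fev1_at_min_age: float = 1.0
    #: post-peak linear decline of the median, liters/year
    decline_rate: dict[str, float] = field(
        default_factory=lambda: {"M": 0.030, "F": 0.022}
    )
    #: marginal log-scale SD of a single FEV1 visit
    fev1_log_sigma: float = 0.32
    #: within-patient-year log-scale SD (must be < fev1_log_sigma)
    within_year_log_sigma: float = 0.07
    #: relative FEV1 increment per cm of height above the age median
    height_effect: float = 0.010
    #: median growth curve per sex as (age, height cm) landmarks, linearly
    #: interpolated — fast infant growth, pubertal spurt, adult plateau
    height_curve: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "M": (
                (0, 50), (1, 76), (2, 87), (4, 103), (6, 116), (8, 128),
                (10, 138), (12, 149), (14, 163), (16, 173), (18, 176),
                (20, 177), (40, 177),
            ),
            "F": (
                (0, 49), (1, 74), (2, 86), (4, 102), (6, 115), (8, 127),
                (10, 138), (12, 151), (14, 160), (16, 162), (18, 163),
                (20, 163), (40, 163),
            ),
        }
    )
    #: SD of height around the median at adult age (shrunk pro rata in children)
    height_sd_cm: float = 6.0
    bmi_lms_curves: dict[str, list[tuple[float, float, float, float]]] = field(
        default_factory=_default_bmi_lms
    )
    visits_per_year: int = 3
    years: tuple[int, ...] = (2004,)
    country_labels: tuple[CountrySpec, ...] = field(default_factory=_default_countries)
    #: fraction of patients flagged post-transplant
    transplant_fraction: float = 0.02
    f508del_hom_fraction: float = 0.48
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_per_sex <= 0:
            raise ValidationError("n_patients_per_sex must be > 0")
        if not self.fev1_log_sigma > 0:
            raise ValidationError("fev1_log_sigma must be > 0")
        if not 0 <= self.within_year_log_sigma < self.fev1_log_sigma:
            raise ValidationError(
                "within_year_log_sigma must be in [0, fev1_log_sigma)"
            )
        for sex in ("M", "F"):
            if not self.peak_median_fev1[sex] > 0:
                raise ValidationError(f"peak_median_fev1[{sex}] must be > 0")
        if self.visits_per_year < 1:
            raise ValidationError("visits_per_year must be >= 1")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 40):
            raise ValidationError("age_range must satisfy 0 <= min < max <= 40")
        if abs(sum(c.weight for c in self.country_labels) - 1.0) > 1e-6:
            raise ValidationError("country weights must sum to 1")

    @property
    def between_log_sigma(self) -> float:
        return math.sqrt(self.fev1_log_sigma**2 - self.within_year_log_sigma**2)


# ---------------------------------------------------------------------------
# closed-form surfaces


def median_height(config: SimConfig, sex: str, age) -> np.ndarray:
    """Median height (cm) at a given age — interpolated growth landmarks."""
    curve = np.asarray(config.height_curve[sex], dtype=float)
    age = np.asarray(age, dtype=float)
    return np.interp(age, curve[:, 0], curve[:, 1])


def median_fev1_age(config: SimConfig, sex: str, age) -> np.ndarray:
    """Median FEV1 (L) at median height: cubic Hermite rise from
    (fev1_min_age, fev1_at_min_age) to the sex-specific peak with zero slope
    at the peak, then linear decline."""
    age = np.asarray(age, dtype=float)
    a_pk = config.peak_age[sex]
    peak = config.peak_median_fev1[sex]
    a0, v0 = config.fev1_min_age, config.fev1_at_min_age
    h = a_pk - a0
    delta = (peak - v0) / h
    # Hermite endpoint slopes (1.5*delta, 0): monotone, near-linear early rise
    t = np.clip((age - a0) / h, 0.0, 1.0)
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    rise = h00 * v0 + h10 * h * (1.5 * delta) + h01 * peak
    decline = peak - config.decline_rate[sex] * (age - a_pk)
    return np.where(age <= a_pk, rise, decline)


def median_fev1(config: SimConfig, sex: str, age, height=None) -> np.ndarray:
    """The median FEV1 surface m(sex, age, height); at median height when
    ``height`` is None."""
    age = np.asarray(age, dtype=float)
    base = median_fev1_age(config, sex, age)
    if height is None:
        return base
    dh = np.asarray(height, dtype=float) - median_height(config, sex, age)
    # clamp the multiplier away from zero so extreme heights stay positive
    return base * np.clip(1.0 + config.height_effect * dh, 0.2, None)


def _interp_lms(
    curve: list[tuple[float, float, float, float]], age
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(curve, dtype=float)
    ages, L, M, S = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    age = np.asarray(age, dtype=float)
    return (
        np.interp(age, ages, L),
        np.interp(age, ages, M),
        np.interp(age, ages, S),
    )


def lms_quantile(L, M, S, tau) -> np.ndarray:
    """Inverse of the LMS z-score transform: the tau-quantile of an LMS law."""
    z = stats.norm.ppf(tau)
    L, M, S = np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    base = np.clip(1.0 + L * S * z, 1e-8, None)  # guard absurd tail draws
    with np.errstate(invalid="ignore"):
        out = np.where(
            L == 0,
            M * np.exp(S * z),
            M * np.power(base, 1.0 / np.where(L == 0, 1.0, L)),
        )
    return out


def true_quantile(
    config: SimConfig,
    outcome: str,
    sex: str,
    tau: float,
    age,
    height=None,
):
    """Ground-truth conditional quantile of the generator.

    FEV1: ``m(sex, age, height) * exp(sigma * Phi^-1(tau))``.
    BMI: the LMS inverse ``M * (1 + L*S*Phi^-1(tau))**(1/L)`` (log form at L=0).
    """
    if not 0 < tau < 1:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    age_arr = np.asarray(age, dtype=float)
    lo, hi = config.age_range
    if np.any(age_arr < lo) or np.any(age_arr > hi):
        raise ValidationError(f"age outside configured range [{lo}, {hi}]")
    if outcome == "fev1":
        m = median_fev1(config, sex, age_arr, height)
        out = m * np.exp(config.fev1_log_sigma * stats.norm.ppf(tau))
    elif outcome == "bmi":
        L, M, S = _interp_lms(config.bmi_lms_curves[sex], age_arr)
        out = lms_quantile(L, M, S, tau)
    else:
        raise ValidationError(f"outcome must be 'fev1' or 'bmi', got {outcome!r}")
    return float(out) if np.isscalar(age) or np.ndim(age) == 0 else out


# ---------------------------------------------------------------------------
# sampling


def sample_fev1_visits(
    config: SimConfig, sex: str, age, height, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k within-year FEV1 visits for each patient-year (rows) — shared
    patient-year effect plus independent visit noise.  The marginal law of
    any single column is log-normal around ``median_fev1``."""
    m = np.atleast_1d(median_fev1(config, sex, age, height))
    n = m.shape[0]
    z_py = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    logv = (
        np.log(m)[:, None]
        + config.between_log_sigma * z_py[:, None]
        + config.within_year_log_sigma * eps
    )
    return np.exp(logv)


def simulate_registry(config: SimConfig) -> Registry:
    """Generate a synthetic registry.

    One record per patient-year: countries flagged ``reports_best`` report
    the maximum of the k within-year visits (``measurement_type='best'``),
    the others a single unselected visit.  All visit-level draws are kept in
    ``registry.longitudinal`` (columns: patient_id, country, year, sex,
    age_years, height_cm, visit, fev1_l) to support estimating the
    best-value correction.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    countries = config.country_labels
    weights = np.array([c.weight for c in countries])
    lo, hi = config.age_range
    year0 = min(config.years)
    k = config.visits_per_year

    frames = []
    long_frames = []
    for sex in ("M", "F"):
        n = config.n_patients_per_sex
        pid = np.array([f"{sex}{i:06d}" for i in range(n)])
        c_idx = rng.choice(len(countries), size=n, p=weights)
        base_age = rng.uniform(lo, hi, size=n)
        transplanted = rng.random(n) < config.transplant_fraction
        geno = np.where(
            rng.random(n) < config.f508del_hom_fraction, "F508del_hom", "other"
        )
        adult_h = median_height(config, sex, np.array([hi]))[0]

        for year in config.years:
            age = base_age + (year - year0)
            keep = age <= hi
            if not np.any(keep):
                continue
            idx = np.flatnonzero(keep)
            a = age[idx]
            h_med = median_height(config, sex, a)
            height = h_med + rng.standard_normal(idx.size) * (
                config.height_sd_cm * h_med / adult_h
            )
            height = np.maximum(height, 0.5 * h_med)
            L, M, S = _interp_lms(config.bmi_lms_curves[sex], a)
            z_bmi = rng.standard_normal(idx.size)
            bmi = lms_quantile(L, M, S, stats.norm.cdf(z_bmi))
            weight = bmi * (height / 100.0) ** 2

            has_fev1 = a >= config.fev1_min_age
            fev1 = np.full(idx.size, np.nan)
            mtype = np.full(idx.size, "unselected", dtype=object)
            if np.any(has_fev1):
                f_idx = np.flatnonzero(has_fev1)
                visits = sample_fev1_visits(
                    config, sex, a[f_idx], height[f_idx], k, rng
                )
                best = visits.max(axis=1)
                unsel = visits[:, 0]
                reports_best = np.array(
                    [countries[c_idx[idx[j]]].reports_best for j in f_idx]
                )
                fev1[f_idx] = np.where(reports_best, best, unsel)
                mtype[f_idx] = np.where(reports_best, "best", "unselected")
                long_frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": np.repeat(pid[idx[f_idx]], k),
                            "country": np.repeat(
                                [countries[c_idx[j]].name for j in idx[f_idx]], k
                            ),
                            "year": year,
                            "sex": sex,
                            "age_years": np.repeat(a[f_idx], k),
                            "height_cm": np.repeat(height[f_idx], k),
                            "visit": np.tile(np.arange(1, k + 1), f_idx.size),
                            "fev1_l": visits.ravel(),
                        }
                    )
                )
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[idx],
                        "country": [countries[c_idx[j]].name for j in idx],
                        "year": year,
                        "sex": sex,
                        "age_years": a,
                        "height_cm": height,
                        "weight_kg": weight,
                        "fev1_l": fev1,
                        "measurement_type": mtype,
                        "transplanted": transplanted[idx],
                        "genotype_class": geno[idx],
                    }
                )
            )

    frame = pd.concat(frames, ignore_index=True)[COLUMNS]
    reg = Registry(
        frame=frame,
        provenance=(
            f"synthetic registry (seed={config.seed}, "
            f"n={config.n_patients_per_sex}/sex, years={list(config.years)}, "
            f"k={k} visits/year)"
        ),
    )
    reg.longitudinal = (
        pd.concat(long_frames, ignore_index=True) if long_frames else None
    )
    return reg
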