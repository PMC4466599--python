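"""Seeded synthetic cohorts of overweight/obese children.

Stands in for the population-based derivation cohorts the risk models
assume: children above the 91st BMI centile with the covariates the models
use (ethnicity-adjusted BMI z-score; bullying and victimisation status;
daily sedentary hours), stylised cardiometabolic biomarkers (fasting
glucose, LDL cholesterol, blood-pressure centiles), an emotional/
behavioural-difficulties score (SDQ total) and two binary outcomes:

* cardiovascular abnormality — any of fasting glucose >= 5.6 mmol/L,
  LDL >= 2.85 mmol/L, or systolic/diastolic BP >= 95th centile;
* emotional/behavioural difficulties — SDQ total > 17.5 (strict).

Outcomes are drawn from a logistic model with configurable effect sizes;
the intercept is solved numerically so the realised prevalence matches the
target in expectation. Biomarkers are then drawn *conditionally on* the
outcome flag (positives are guaranteed at least one marker over its
threshold), so the definitional operations reproduce the generated flags
for every child. All randomness flows from one explicit seed.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigurationError, UnsatisfiableConfigError, ValidationError
from .growth import ReferenceTable, centile_to_zscore, lms_inverse
from .records import ChildRecord, Ethnicity, Sex

GLUCOSE_THRESHOLD = 5.6  # mmol/L
LDL_THRESHOLD = 2.85  # mmol/L
BP_CENTILE_THRESHOLD = 95.0  # percent
SDQ_THRESHOLD = 17.5  # strict: > 17.5 flags raised probability of disorder

#: canonical column order of the cohort CSV dialect
COHORT_COLUMNS = [
    "age",
    "sex",
    "ethnicity",
    "height_cm",
    "weight_kg",
    "bmi",
    "adjusted_bmi_z",
    "bullied",
    "victimised",
    "sedentary_hours",
    "glucose_mmol_l",
    "ldl_mmol_l",
    "sbp_centile",
    "dbp_centile",
    "sdq_total",
    "cardio_outcome",
    "ebd_outcome",
]


def define_cardio_outcome(
    glucose: float, ldl: float, sbp_centile: float, dbp_centile: float
) -> bool:
    """True iff any cardiometabolic marker meets its (inclusive) threshold."""
    return bool(
        glucose >= GLUCOSE_THRESHOLD
        or ldl >= LDL_THRESHOLD
        or sbp_centile >= BP_CENTILE_THRESHOLD
        or dbp_centile >= BP_CENTILE_THRESHOLD
    )


def define_ebd_outcome(sdq_total: float) -> bool:
    """True iff the SDQ total strictly exceeds 17.5."""
    if sdq_total < 0:
        raise ValidationError("sdq_total must be >= 0")
    return bool(sdq_total > SDQ_THRESHOLD)


class CohortConfig(BaseModel):
    """Generator settings; the defaults are the package's study conditions."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=1)
    seed: int
    cardio_prevalence: float = Field(default=0.10, ge=0.0, le=1.0)
    ebd_prevalence: float = Field(default=0.10, ge=0.0, le=1.0)
    cardio_effects: dict[str, float] = {"adjusted_bmi_z": 0.9}
    ebd_effects: dict[str, float] = {"bullied": 0.9, "victimised": 0.7, "sedentary_hours": 0.18}
    bullied_rate: float = Field(default=0.25, ge=0.0, le=1.0)
    victimised_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    sedentary_shape: float = Field(default=3.0, gt=0.0)
    sedentary_scale: float = Field(default=1.0, gt=0.0)
    bmi_z_mean: float = 2.0
    bmi_z_sd: float = Field(default=0.6, gt=0.0)
    min_bmi_centile: float = Field(default=91.0, gt=0.0, lt=100.0)
    n_null_covariates: int = Field(default=0, ge=0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclasses.dataclass
class SyntheticChild:
    """One simulated child: record fields, biomarkers and derived outcomes."""

    age: float
    sex: Sex
    ethnicity: Ethnicity
    height_cm: float
    weight_kg: float
    bmi: float
    adjusted_bmi_z: float
    bullied: bool
    victimised: bool
    sedentary_hours: float
    lifestyle: dict[str, float]
    glucose_mmol_l: float
    ldl_mmol_l: float
    sbp_centile: float
    dbp_centile: float
    sdq_total: float
    cardio_outcome: bool
    ebd_outcome: bool

    def to_child_record(self) -> ChildRecord:
        return ChildRecord(
            age=self.age,
            sex=self.sex,
            ethnicity=self.ethnicity,
            height_cm=self.height_cm,
            weight_kg=self.weight_kg,
            lifestyle=dict(self.lifestyle),
            bullied=self.bullied,
            victimised=self.victimised,
            sedentary_hours=self.sedentary_hours,
        )


def _trunc_norm(rng, mu, sd, lo=-np.inf, hi=np.inf, size=None):
    """Truncated normal via inverse-CDF so all draws flow through ``rng``."""
    a = norm.cdf((lo - mu) / sd)
    b = norm.cdf((hi - mu) / sd)
    u = rng.uniform(a, b, size=size)
    return mu + sd * norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def solve_intercept(X: np.ndarray, beta: np.ndarray, prevalence: float) -> float:
    """Intercept making mean(expit(b0 + X @ beta)) equal the target prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise UnsatisfiableConfigError(
            f"target prevalence {prevalence} not attainable by a logistic model "
            "(must lie strictly between 0 and 1)"
        )
    eta = X @ beta

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)) - prevalence)

    return float(brentq(gap, -60.0, 60.0, xtol=1e-10))


def _effects_vector(effects: dict[str, float], frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    unknown = [k for k in effects if k not in frame.columns]
    if unknown:
        raise ConfigurationError(f"effect size(s) refer to unknown covariate(s): {unknown}")
    names = list(effects)
    X = frame[names].to_numpy(float)
    beta = np.array([effects[k] for k in names], dtype=float)
    return X, beta


def generate_cohort(
    config: CohortConfig, reference: Optional[ReferenceTable] = None
) -> list[SyntheticChild]:
    """Generate a seeded cohort of overweight/obese children.

    Identical seeds produce identical cohorts. BMI values are obtained by
    inverting the growth reference's LMS curves at z-scores truncated above
    the configured minimum centile (91st by default), so every child is
    overweight or obese by construction.
    """
    return _generate(config, reference)[0]


def _generate(
    config: CohortConfig, reference: Optional[ReferenceTable] = None
) -> tuple[list[SyntheticChild], pd.DataFrame]:
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = ReferenceTable.load_packaged()
    n = config.n

    lo_age, hi_age = reference.age_range(Sex.male)
    age = rng.uniform(lo_age, hi_age, n)
    sex = rng.choice([Sex.male.value, Sex.female.value], size=n)
    eth = rng.choice(
        [e.value for e in Ethnicity], size=n, p=[0.30, 0.35, 0.25, 0.10]
    )
    z_floor = centile_to_zscore(config.min_bmi_centile)
    z = _trunc_norm(rng, config.bmi_z_mean, config.bmi_z_sd, lo=z_floor, size=n)
    bmi = np.array(
        [lms_inverse(z[i], *reference.lms(age[i], sex[i])) for i in range(n)]
    )
    height = _trunc_norm(rng, 110.0 + 5.0 * (age - 5.0), 6.0, lo=80.0, size=n)
    weight = bmi * (height / 100.0) ** 2

    bullied = rng.random(n) < config.bullied_rate
    victimised = rng.random(n) < config.victimised_rate
    sedentary = rng.gamma(config.sedentary_shape, config.sedentary_scale, n)

    frame = pd.DataFrame(
        {
            "adjusted_bmi_z": z,  # ethnicity offsets default to zero
            "bullied": bullied.astype(float),
            "victimised": victimised.astype(float),
            "sedentary_hours": sedentary,
        }
    )
    for j in range(config.n_null_covariates):
        frame[f"noise_{j + 1}"] = rng.normal(0.0, 1.0, n)

    def draw_outcome(effects: dict[str, float], prevalence: float) -> np.ndarray:
        X, beta = _effects_vector(effects, frame)
        b0 = solve_intercept(X, beta, prevalence)
        return rng.random(n) < expit(b0 + X @ beta)

    cardio = draw_outcome(config.cardio_effects, config.cardio_prevalence)
    ebd = draw_outcome(config.ebd_effects, config.ebd_prevalence)

    # biomarkers conditional on the flags, so the definitional thresholds
    # reproduce the generated outcomes exactly
    below = np.nextafter(GLUCOSE_THRESHOLD, -np.inf)
    glucose = _trunc_norm(rng, 4.9, 0.45, lo=3.2, hi=below, size=n)
    ldl = _trunc_norm(rng, 2.2, 0.35, lo=0.8, hi=np.nextafter(LDL_THRESHOLD, -np.inf), size=n)
    bp_hi = np.nextafter(BP_CENTILE_THRESHOLD, -np.inf)
    sbp = _trunc_norm(rng, 62.0, 18.0, lo=0.5, hi=bp_hi, size=n)
    dbp = _trunc_norm(rng, 58.0, 18.0, lo=0.5, hi=bp_hi, size=n)
    which = rng.integers(0, 4, size=n)  # which marker is elevated for positives
    elevated = {
        0: _trunc_norm(rng, 5.9, 0.35, lo=GLUCOSE_THRESHOLD, hi=8.5, size=n),
        1: _trunc_norm(rng, 3.1, 0.30, lo=LDL_THRESHOLD, hi=5.5, size=n),
        2: _trunc_norm(rng, 97.0, 1.5, lo=BP_CENTILE_THRESHOLD, hi=99.9, size=n),
        3: _trunc_norm(rng, 97.0, 1.5, lo=BP_CENTILE_THRESHOLD, hi=99.9, size=n),
    }
    glucose = np.where(cardio & (which == 0), elevated[0], glucose)
    ldl = np.where(cardio & (which == 1), elevated[1], ldl)
    sbp = np.where(cardio & (which == 2), elevated[2], sbp)
    dbp = np.where(cardio & (which == 3), elevated[3], dbp)

    sdq = np.where(
        ebd,
        _trunc_norm(rng, 21.0, 3.0, lo=np.nextafter(SDQ_THRESHOLD, np.inf), hi=40.0, size=n),
        _trunc_norm(rng, 9.0, 4.0, lo=0.0, hi=SDQ_THRESHOLD, size=n),
    )

    fruit_veg = rng.integers(0, 8, n).astype(float)
    mvpa = rng.gamma(2.5, 20.0, n)
    sleep = _trunc_norm(rng, 9.0, 1.0, lo=5.0, hi=12.0, size=n)
    sugary = rng.integers(0, 4, n).astype(float)
    breakfast = rng.integers(0, 8, n).astype(float)

    children = []
    for i in range(n):
        children.append(
            SyntheticChild(
                age=float(age[i]),
                sex=Sex(sex[i]),
                ethnicity=Ethnicity(eth[i]),
                height_cm=float(height[i]),
                weight_kg=float(weight[i]),
                bmi=float(bmi[i]),
                adjusted_bmi_z=float(z[i]),
                bullied=bool(bullied[i]),
                victimised=bool(victimised[i]),
                sedentary_hours=float(sedentary[i]),
                lifestyle={
                    "fruit_veg_portions": float(fruit_veg[i]),
                    "mvpa_minutes": float(mvpa[i]),
                    "screen_hours": float(round(sedentary[i], 1)),
                    "sugary_drinks": float(sugary[i]),
                    "sleep_hours": float(sleep[i]),
                    "breakfast_days": float(breakfast[i]),
                },
                glucose_mmol_l=float(glucose[i]),
                ldl_mmol_l=float(ldl[i]),
                sbp_centile=float(sbp[i]),
                dbp_centile=float(dbp[i]),
                sdq_total=float(sdq[i]),
                cardio_outcome=bool(cardio[i]),
                ebd_outcome=bool(ebd[i]),
            )
        )
    noise_cols = frame[[c for c in frame.columns if c.startswith("noise_")]].copy()
    return children, noise_cols


def cohort_to_frame(children: Sequence[SyntheticChild]) -> pd.DataFrame:
    """Flatten a cohort into the CSV dialect consumed by the risk module."""
    rows = []
    for c in children:
        row = {
            "age": c.age,
            "sex": c.sex.value,
            "ethnicity": c.ethnicity.value,
            "height_cm": c.height_cm,
            "weight_kg": c.weight_kg,
            "bmi": c.bmi,
            "adjusted_bmi_z": c.adjusted_bmi_z,
            "bullied": int(c.bullied),
            "victimised": int(c.victimised),
            "sedentary_hours": c.sedentary_hours,
            "glucose_mmol_l": c.glucose_mmol_l,
            "ldl_mmol_l": c.ldl_mmol_l,
            "sbp_centile": c.sbp_centile,
            "dbp_centile": c.dbp_centile,
            "sdq_total": c.sdq_total,
            "cardio_outcome": int(c.cardio_outcome),
            "ebd_outcome": int(c.ebd_outcome),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def generate_cohort_frame(
    config: CohortConfig, reference: Optional[ReferenceTable] = None
) -> pd.DataFrame:
    """Generate a cohort directly as a DataFrame (includes any noise columns)."""
    children, noise = _generate(config, reference)
    frame = cohort_to_frame(children)
    for col in noise.columns:
        frame[col] = noise[col].to_numpy()
    return frame


def write_cohort_csv(children_or_frame, path: str | Path) -> None:
    frame = (
        children_or_frame
        if isinstance(children_or_frame, pd.DataFrame)
        else cohort_to_frame(children_or_frame)
    )
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, rejecting missing values with row-numbered errors."""
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)]
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-basing
        raise ValidationError(f"cohort CSV has missing values (file line(s) {rows})")
    return frame
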