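"""BMI, LMS z-scores, centiles and weight-status classification.

The LMS method summarises an age/sex growth reference by three smooth
curves: the Box–Cox power L(t) absorbing skewness, the median M(t) and the
coefficient of variation S(t). For a measurement ``x`` at age ``t`` the
standard-deviation score is

    z = ((x / M)**L - 1) / (L * S)        if |L| > 0
    z = ln(x / M) / S                     as L -> 0 (removable singularity)

and the centile is 100 * Phi(z). UK clinical practice classifies a child's
BMI as overweight at or above the 91st centile and obese at or above the
98th centile of the British 1990 (UK90) reference. The UK90 tables are
externally licensed, so the package ships a *synthetic* reference with the
same structure for testing and demonstration; users supply a licensed
reference CSV for clinical use.
"""
from __future__ import annotations

import dataclasses
import enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, OutOfRangeError, ValidationError
from .records import ChildRecord, Ethnicity, Sex

#: |L| at or below this triggers the logarithmic z-score branch.
L_LOG_TOLERANCE = 1e-8

OVERWEIGHT_CENTILE = 91.0
OBESE_CENTILE = 98.0

_REFERENCE_COLUMNS = ["age_years", "sex", "L", "M", "S"]


class WeightCategory(str, enum.Enum):
    healthy = "healthy"
    overweight = "overweight"
    obese = "obese"


@dataclasses.dataclass(frozen=True)
class WeightStatus:
    """Weight-status classification for one child."""

    category: WeightCategory
    bmi: float
    z: float
    centile: float


class ReferenceTable:
    """Per-sex, per-age LMS parameters defining a growth reference.

    Invariants enforced on construction: M > 0 and S > 0 everywhere, ages
    strictly increasing within each sex, and at least two rows per sex.
    """

    def __init__(self, frame: pd.DataFrame, name: str = "reference"):
        missing = [c for c in _REFERENCE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"reference table missing columns: {missing}")
        frame = frame[_REFERENCE_COLUMNS].copy()
        bad_sex = set(frame["sex"]) - {s.value for s in Sex}
        if bad_sex:
            raise ValidationError(f"reference table has unknown sex values: {sorted(bad_sex)}")
        if (frame["M"] <= 0).any():
            raise ValidationError("reference table column M must be > 0 in every row")
        if (frame["S"] <= 0).any():
            raise ValidationError("reference table column S must be > 0 in every row")
        self.name = name
        self._by_sex: dict[str, pd.DataFrame] = {}
        for sex in Sex:
            sub = frame[frame["sex"] == sex.value].reset_index(drop=True)
            if len(sub) < 2:
                raise ValidationError(f"reference table needs >= 2 rows for sex={sex.value}")
            ages = sub["age_years"].to_numpy(float)
            if not np.all(np.diff(ages) > 0):
                raise ValidationError(f"ages must be strictly increasing for sex={sex.value}")
            self._by_sex[sex.value] = sub
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        """Read a reference CSV with header ``age_years,sex,L,M,S``."""
        return cls(pd.read_csv(path), name=Path(path).stem)

    @classmethod
    def load_packaged(cls) -> "ReferenceTable":
        """Load the packaged synthetic reference (not UK90; testing/demo only)."""
        with resources.files("childcheck.data").joinpath(
            "synthetic_lms_reference.csv"
        ).open("r") as fh:
            return cls(pd.read_csv(fh), name="synthetic_lms_reference")

    def age_range(self, sex: Sex | str) -> tuple[float, float]:
        sub = self._by_sex[Sex(sex).value]
        ages = sub["age_years"].to_numpy(float)
        return float(ages[0]), float(ages[-1])

    def lms(self, age: float, sex: Sex | str) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age`` for ``sex``.

        Exact table rows are reproduced at grid ages; ages outside the
        tabulated range raise :class:`OutOfRangeError` (no extrapolation).
        """
        sub = self._by_sex[Sex(sex).value]
        ages = sub["age_years"].to_numpy(float)
        if not (ages[0] <= age <= ages[-1]):
            raise OutOfRangeError(
                f"age {age:g} y outside reference range "
                f"[{ages[0]:g}, {ages[-1]:g}] for sex={Sex(sex).value}"
            )
        return tuple(
            float(np.interp(age, ages, sub[col].to_numpy(float))) for col in ("L", "M", "S")
        )


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m² from weight (kg) and height (cm)."""
    if weight_kg <= 0:
        raise ValidationError("weight_kg must be > 0")
    if height_cm <= 0:
        raise ValidationError("height_cm must be > 0")
    h = height_cm / 100.0
    return weight_kg / (h * h)


def interpolate_lms(table: ReferenceTable, age: float, sex: Sex | str) -> tuple[float, float, float]:
    """Functional alias for :meth:`ReferenceTable.lms`."""
    return table.lms(age, sex)


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS standard-deviation score of measurement ``x``.

    Uses the logarithmic branch when |L| <= ``L_LOG_TOLERANCE``; the two
    branches agree continuously at L = 0.
    """
    if x <= 0:
        raise ValidationError("measurement x must be > 0")
    if M <= 0:
        raise ValidationError("M must be > 0")
    if S <= 0:
        raise ValidationError("S must be > 0")
    if abs(L) <= L_LOG_TOLERANCE:
        return float(np.log(x / M) / S)
    return float(((x / M) ** L - 1.0) / (L * S))


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement with standard-deviation score ``z`` (inverse of lms_zscore)."""
    if M <= 0 or S <= 0:
        raise ValidationError("M and S must be > 0")
    if abs(L) <= L_LOG_TOLERANCE:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValidationError("z outside the representable range for these LMS values")
    return float(M * base ** (1.0 / L))


def zscore_to_centile(z: float) -> float:
    """Centile (percent) = 100 * Phi(z)."""
    return float(100.0 * norm.cdf(z))


def centile_to_zscore(percent: float) -> float:
    """Normal-equivalent deviate of a centile in the open interval (0, 100)."""
    if not (0.0 < percent < 100.0):
        raise ValidationError("percent must lie strictly between 0 and 100")
    return float(norm.ppf(percent / 100.0))


def ethnicity_adjusted_zscore(
    z: float,
    ethnicity: Ethnicity | str,
    offsets: Optional[Mapping[str, float]] = None,
) -> float:
    """Additive ethnicity adjustment of a BMI z-score.

    The adjustment is a configurable per-ethnicity shift, defaulting to zero
    for every group; it preserves within-group rank order by construction.
    """
    key = Ethnicity(ethnicity).value
    if offsets is None:
        return float(z)
    if key not in offsets:
        raise ConfigurationError(f"no ethnicity offset configured for {key!r}")
    return float(z + offsets[key])


def weight_category_from_centile(centile: float) -> WeightCategory:
    """Category from BMI centile; boundaries classify upward (>=91, >=98)."""
    if centile >= OBESE_CENTILE:
        return WeightCategory.obese
    if centile >= OVERWEIGHT_CENTILE:
        return WeightCategory.overweight
    return WeightCategory.healthy


def classify_weight_status(record: ChildRecord, table: ReferenceTable) -> WeightStatus:
    """BMI, z-score, centile and category for one child against a reference."""
    bmi = compute_bmi(record.weight_kg, record.height_cm)
    L, M, S = table.lms(record.age, record.sex)
    z = lms_zscore(bmi, L, M, S)
    centile = zscore_to_centile(z)
    return WeightStatus(
        category=weight_category_from_centile(centile), bmi=bmi, z=z, centile=centile
    )
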