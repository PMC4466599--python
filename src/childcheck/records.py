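"""Patient-facing record types.

A :class:`ChildRecord` carries everything a single consultation needs:
demographics, measured anthropometry, patient-reported lifestyle behaviours
and the psychosocial items the emotional/behavioural risk model uses
(bullying, victimisation, daily sedentary hours).
"""
from __future__ import annotations

import enum
import json
import warnings
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator

CONSULTATION_AGE_MIN = 5.0
CONSULTATION_AGE_MAX = 18.0


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Ethnicity(str, enum.Enum):
    White = "White"
    Asian = "Asian"
    Black = "Black"
    Other = "Other"


class ChildRecord(BaseModel):
    """One child's consultation inputs.

    Ages are decimal years; callers converting from dates must use
    ``(date - birthdate) / 365.25``. Ages outside the 5–18 y consultation
    band are accepted with a warning (the growth reference may still reject
    them).
    """

    model_config = ConfigDict(extra="forbid")

    age: float
    sex: Sex
    ethnicity: Ethnicity = Ethnicity.Other
    height_cm: float
    weight_kg: float
    lifestyle: dict[str, float] = {}
    bullied: Optional[bool] = None
    victimised: Optional[bool] = None
    sedentary_hours: Optional[float] = None

    @field_validator("height_cm")
    @classmethod
    def _height_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("height_cm must be > 0")
        return v

    @field_validator("weight_kg")
    @classmethod
    def _weight_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("weight_kg must be > 0")
        return v

    @field_validator("sedentary_hours")
    @classmethod
    def _sedentary_non_negative(cls, v):
        if v is not None and v < 0:
            raise ValueError("sedentary_hours must be >= 0")
        return v

    @field_validator("age")
    @classmethod
    def _age_band(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("age must be > 0")
        if not (CONSULTATION_AGE_MIN <= v <= CONSULTATION_AGE_MAX):
            warnings.warn(
                f"age {v:g} y is outside the 5-18 y consultation band",
                stacklevel=2,
            )
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "ChildRecord":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def risk_covariates(self, adjusted_bmi_z: float) -> dict[str, float]:
        """Numeric covariate map consumed by the risk models.

        Booleans become 0/1; unreported items are simply absent, so a model
        requiring them raises a named-field error downstream.
        """
        cov: dict[str, float] = {"adjusted_bmi_z": float(adjusted_bmi_z)}
        if self.bullied is not None:
            cov["bullied"] = float(self.bullied)
        if self.victimised is not None:
            cov["victimised"] = float(self.victimised)
        if self.sedentary_hours is not None:
            cov["sedentary_hours"] = float(self.sedentary_hours)
        return cov
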