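"""The three-step consultation and questionnaire summaries.

A consultation composes, in order: (1) weight-status assessment against the
growth reference, (2) comorbidity risk scoring and Low/Medium/High
stratification (a High stratum on either outcome adds a referral
recommendation), and (3) personalised lifestyle advice. The report is
serialisable to text, HTML and JSON; a normalised mode excludes the
timestamp so identical inputs yield byte-identical output.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import html as _html
import json
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import ConsultationError, ValidationError
from .growth import (
    ReferenceTable,
    WeightStatus,
    classify_weight_status,
    ethnicity_adjusted_zscore,
    lms_inverse,
    centile_to_zscore,
)
from .lifestyle import AdviceReport, LifestyleRule, generate_advice
from .records import ChildRecord
from .risk import RiskLevel, RiskModel, RiskStrata

DEFAULT_REFERRAL_TEXT = (
    "High risk: recommend further assessment or referral to specialist services."
)
_RISK_ADVICE = {
    RiskLevel.Low: "Low risk: reassure and reinforce healthy habits.",
    RiskLevel.Medium: "Medium risk: discuss lifestyle changes and review at a later visit.",
    RiskLevel.High: DEFAULT_REFERRAL_TEXT,
}

#: centile curves drawn on the BMI chart
CHART_CENTILES = (2.0, 9.0, 25.0, 50.0, 75.0, 91.0, 98.0)


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class RiskAssessment:
    outcome_name: str
    score: float
    stratum: RiskLevel
    recommendation: str


@dataclasses.dataclass
class ConsultationReport:
    """Full consultation output: weight, risk and lifestyle sections."""

    weight: WeightStatus
    chart_points: dict[str, list[tuple[float, float]]]
    child_point: tuple[float, float]
    risk: list[RiskAssessment]
    lifestyle: AdviceReport
    metadata: dict

    def to_dict(self, normalised: bool = False) -> dict:
        meta = dict(self.metadata)
        if normalised:
            meta.pop("timestamp", None)
        return {
            "weight": {
                "category": self.weight.category.value,
                "bmi": self.weight.bmi,
                "z": self.weight.z,
                "centile": self.weight.centile,
                "chart_centiles": {k: v for k, v in self.chart_points.items()},
                "child_point": list(self.child_point),
            },
            "risk": [
                {
                    "outcome": r.outcome_name,
                    "score": r.score,
                    "stratum": r.stratum.value,
                    "recommendation": r.recommendation,
                }
                for r in self.risk
            ],
            "lifestyle": {
                "entries": [dataclasses.asdict(e) for e in self.lifestyle.entries],
                "needing_improvement": self.lifestyle.needing_improvement,
            },
            "metadata": meta,
        }

    def to_json(self, normalised: bool = False) -> str:
        return json.dumps(self.to_dict(normalised=normalised), indent=2) + "\n"

    def to_text(self, normalised: bool = False) -> str:
        w = self.weight
        lines = [
            "Consultation report",
            "===================",
            "",
            "1. Weight status",
            f"   BMI: {w.bmi:.1f} kg/m2  z: {w.z:.2f}  centile: {w.centile:.1f}",
            f"   Category: {w.category.value}",
            "",
            "2. Risk assessment",
        ]
        for r in self.risk:
            lines.append(
                f"   {r.outcome_name}: score {r.score:.3f} -> {r.stratum.value}"
            )
            lines.append(f"   {r.recommendation}")
        lines += ["", "3. " + self.lifestyle.to_text().rstrip("\n")]
        if not normalised and "timestamp" in self.metadata:
            lines += ["", f"Generated: {self.metadata['timestamp']}"]
        lines += ["", f"Engine version: {self.metadata.get('version', '')}"]
        return "\n".join(lines) + "\n"

    def to_html(self, normalised: bool = False) -> str:
        w = self.weight
        parts = [
            "<html><body>",
            "<h1>Consultation report</h1>",
            "<h2>1. Weight status</h2>",
            f"<p>BMI {w.bmi:.1f} kg/m&sup2;; z {w.z:.2f}; centile {w.centile:.1f}; "
            f"category <strong>{_html.escape(w.category.value)}</strong></p>",
            "<h2>2. Risk assessment</h2>",
            "<ul>",
        ]
        for r in self.risk:
            parts.append(
                f"<li>{_html.escape(r.outcome_name)}: score {r.score:.3f} "
                f"&rarr; {r.stratum.value}. {_html.escape(r.recommendation)}</li>"
            )
        parts += ["</ul>", "<h2>3. Lifestyle advice</h2>", self.lifestyle.to_html()]
        if not normalised and "timestamp" in self.metadata:
            parts.append(f"<p>Generated: {_html.escape(str(self.metadata['timestamp']))}</p>")
        parts.append("</body></html>")
        return "\n".join(parts) + "\n"


def _chart_points(table: ReferenceTable, sex) -> dict[str, list[tuple[float, float]]]:
    sub = table.frame[table.frame["sex"] == (sex.value if hasattr(sex, "value") else sex)]
    ages = sub["age_years"].to_numpy(float)
    out: dict[str, list[tuple[float, float]]] = {}
    for centile in CHART_CENTILES:
        z = centile_to_zscore(centile)
        pts = []
        for _, row in sub.iterrows():
            pts.append((float(row["age_years"]), lms_inverse(z, row["L"], row["M"], row["S"])))
        out[f"{centile:g}"] = pts
    return out


def run_consultation(
    record: ChildRecord,
    reference: ReferenceTable,
    models: Sequence[RiskModel],
    strata: Mapping[str, RiskStrata],
    ruleset: Sequence[LifestyleRule],
    ethnicity_offsets: Optional[Mapping[str, float]] = None,
    referral_text: str = DEFAULT_REFERRAL_TEXT,
    timestamp: Optional[str] = None,
) -> ConsultationReport:
    """Run the full three-step consultation for one child.

    ``strata`` maps each model's ``outcome_name`` to its calibrated cut-off
    pair. Any component failure aborts with a section-labelled
    :class:`ConsultationError`; no partial report is emitted.
    """
    try:
        status = classify_weight_status(record, reference)
        chart = _chart_points(reference, record.sex)
    except Exception as exc:  # noqa: BLE001 - re-labelled with the section
        raise ConsultationError("weight", exc) from exc

    try:
        adjusted = ethnicity_adjusted_zscore(status.z, record.ethnicity, ethnicity_offsets)
        covariates = record.risk_covariates(adjusted)
        assessments = []
        for model in models:
            if model.outcome_name not in strata:
                raise ValidationError(f"no strata provided for outcome {model.outcome_name!r}")
            score = model.predict(covariates)
            stratum = strata[model.outcome_name].classify(score)
            rec = referral_text if stratum is RiskLevel.High else _RISK_ADVICE[stratum]
            assessments.append(
                RiskAssessment(
                    outcome_name=model.outcome_name,
                    score=score,
                    stratum=stratum,
                    recommendation=rec,
                )
            )
    except ConsultationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ConsultationError("risk", exc) from exc

    try:
        advice = generate_advice(record, ruleset)
    except Exception as exc:  # noqa: BLE001
        raise ConsultationError("lifestyle", exc) from exc

    metadata = {
        "version": __version__,
        "timestamp": timestamp or _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "reference": reference.name,
        "models": [m.outcome_name for m in models],
    }
    return ConsultationReport(
        weight=status,
        chart_points=chart,
        child_point=(record.age, status.bmi),
        risk=assessments,
        lifestyle=advice,
        metadata=metadata,
    )


@dataclasses.dataclass
class QuestionnaireSummary:
    """Frequency counts and rounded proportions for ordinal questionnaire items."""

    n_respondents: int
    item_counts: dict[str, dict[str, int]]
    item_percents: dict[str, dict[str, int]]
    satisfaction_item: Optional[str]
    satisfaction_count: Optional[int]
    satisfaction_percent: Optional[int]


def summarize_questionnaire(
    responses: pd.DataFrame,
    scale: Sequence[str],
    satisfied_levels: Iterable[str] = (),
    satisfaction_item: Optional[str] = None,
) -> QuestionnaireSummary:
    """Per-item frequency counts plus a satisfaction proportion.

    Every response must belong to the declared ordinal ``scale`` (violations
    raise row-numbered errors). The satisfaction proportion is the share of
    respondents whose answer on ``satisfaction_item`` (default: the single
    column, if there is only one) falls in ``satisfied_levels``, rounded
    half-up to integer percent — e.g. 12 of 14 -> 86%.
    """
    if responses.empty:
        raise ValidationError("responses table is empty")
    scale = list(scale)
    satisfied = set(satisfied_levels)
    unknown_levels = satisfied - set(scale)
    if unknown_levels:
        raise ValidationError(f"satisfied_levels not in scale: {sorted(unknown_levels)}")
    for col in responses.columns:
        for pos, value in enumerate(responses[col]):
            if pd.isna(value):
                continue
            if value not in scale:
                raise ValidationError(
                    f"row {pos + 1}, item {col!r}: response {value!r} outside declared scale"
                )
    n = len(responses)
    counts = {
        col: {
            level: int((responses[col] == level).sum()) for level in scale
        }
        for col in responses.columns
    }
    percents = {
        col: {
            level: int(_round_half_up(100.0 * c / n))
            for level, c in per_level.items()
        }
        for col, per_level in counts.items()
    }
    sat_item = satisfaction_item
    if sat_item is None and len(responses.columns) == 1:
        sat_item = responses.columns[0]
    sat_count = sat_pct = None
    if satisfied and sat_item is not None:
        if sat_item not in responses.columns:
            raise ValidationError(f"satisfaction_item {sat_item!r} not in responses")
        sat_count = int(responses[sat_item].isin(satisfied).sum())
        sat_pct = int(_round_half_up(100.0 * sat_count / n))
    return QuestionnaireSummary(
        n_respondents=n,
        item_counts=counts,
        item_percents=percents,
        satisfaction_item=sat_item,
        satisfaction_count=sat_count,
        satisfaction_percent=sat_pct,
    )


def categorical_summary(values: Iterable, decimals: int = 1) -> dict[str, dict[str, float]]:
    """Count/percent breakdown of one categorical variable.

    Percentages are rounded half-up to ``decimals`` places (one decimal by
    default, matching participant-characteristics tables such as 1/14 ->
    7.1%).
    """
    series = pd.Series(list(values))
    if series.empty:
        raise ValidationError("no values to summarise")
    n = len(series)
    out: dict[str, dict[str, float]] = {}
    for level, count in series.value_counts(sort=False).items():
        out[str(level)] = {
            "count": int(count),
            "percent": _round_half_up(100.0 * count / n, decimals),
        }
    return out
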