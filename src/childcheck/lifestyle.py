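"""Rule-based personalised lifestyle advice.

Each rule compares one patient-reported behaviour (fruit/vegetable
portions, activity minutes, screen time, sleep, ...) against a recommended
level with an ``at_least`` or ``at_most`` comparator. Meeting the level
(boundary inclusive) yields an encouraging message; missing it flags the
behaviour as an area needing improvement and renders a modification
suggestion. Recommended levels live in configuration — the packaged default
ruleset carries placeholder levels drawn from common public-health guidance
and is meant to be edited, not treated as authoritative.
"""
from __future__ import annotations

import dataclasses
import html
from importlib import resources
from pathlib import Path
from string import Template
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError, ValidationError
from .records import ChildRecord

_COMPARATORS = ("at_least", "at_most")


@dataclasses.dataclass(frozen=True)
class AgeBand:
    min_age: float
    max_age: float
    level: float


@dataclasses.dataclass(frozen=True)
class LifestyleRule:
    """One behaviour rule; ``age_bands`` (if set) override ``recommended_level``."""

    behaviour_id: str
    comparator: str
    recommended_level: Optional[float]
    units: str
    encouragement_text: str
    advice_text: str
    label: Optional[str] = None
    age_bands: tuple[AgeBand, ...] = ()

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ConfigurationError(
                f"rule {self.behaviour_id!r}: comparator must be one of {_COMPARATORS}"
            )
        if not self.age_bands and self.recommended_level is None:
            raise ConfigurationError(
                f"rule {self.behaviour_id!r}: needs recommended_level or age_bands"
            )

    def effective_level(self, age: Optional[float] = None) -> float:
        if self.age_bands:
            if age is None:
                raise ValidationError(
                    f"rule {self.behaviour_id!r} is age-banded; age is required"
                )
            for band in self.age_bands:
                if band.min_age <= age <= band.max_age:
                    return band.level
            raise ConfigurationError(
                f"rule {self.behaviour_id!r}: no age band covers age {age:g}"
            )
        assert self.recommended_level is not None
        return self.recommended_level


@dataclasses.dataclass(frozen=True)
class AdviceEntry:
    behaviour_id: str
    reported: Optional[float]
    recommended: Optional[float]
    meets_recommendation: Optional[bool]  # None = not assessed
    message: str


@dataclasses.dataclass
class AdviceReport:
    """Per-behaviour outcomes plus the list of behaviours needing improvement."""

    entries: list[AdviceEntry]

    @property
    def needing_improvement(self) -> list[str]:
        return [e.behaviour_id for e in self.entries if e.meets_recommendation is False]

    def to_text(self) -> str:
        lines = ["Lifestyle advice", "----------------"]
        for e in self.entries:
            status = {True: "OK", False: "IMPROVE", None: "NOT ASSESSED"}[
                e.meets_recommendation
            ]
            lines.append(f"[{status}] {e.behaviour_id}: {e.message}")
        if self.needing_improvement:
            lines.append("Areas needing improvement: " + ", ".join(self.needing_improvement))
        else:
            lines.append("Areas needing improvement: none")
        return "\n".join(lines) + "\n"

    def to_html(self) -> str:
        rows = []
        for e in self.entries:
            status = {True: "meets", False: "improve", None: "not-assessed"}[
                e.meets_recommendation
            ]
            rows.append(
                f'<li class="{status}"><strong>{html.escape(e.behaviour_id)}</strong>: '
                f"{html.escape(e.message)}</li>"
            )
        return "<ul>\n" + "\n".join(rows) + "\n</ul>\n"


def _render(template: str, reported, recommended, rule: LifestyleRule) -> str:
    return Template(template).safe_substitute(
        reported=f"{reported:g}" if reported is not None else "not reported",
        recommended=f"{recommended:g}" if recommended is not None else "",
        units=rule.units,
        behaviour=rule.label or rule.behaviour_id,
    )


def evaluate_rule(
    reported: Optional[float],
    rule: LifestyleRule,
    age: Optional[float] = None,
) -> AdviceEntry:
    """Evaluate one behaviour; missing reports yield a 'not assessed' entry.

    ``at_least`` is met iff reported >= level; ``at_most`` iff reported <=
    level (boundary inclusive in both directions).
    """
    if reported is None:
        return AdviceEntry(
            behaviour_id=rule.behaviour_id,
            reported=None,
            recommended=None,
            meets_recommendation=None,
            message="not assessed (no value reported)",
        )
    level = rule.effective_level(age)
    meets = reported >= level if rule.comparator == "at_least" else reported <= level
    template = rule.encouragement_text if meets else rule.advice_text
    return AdviceEntry(
        behaviour_id=rule.behaviour_id,
        reported=float(reported),
        recommended=float(level),
        meets_recommendation=bool(meets),
        message=_render(template, reported, level, rule),
    )


def generate_advice(record: ChildRecord, ruleset: Sequence[LifestyleRule]) -> AdviceReport:
    """Apply every rule to one child, in ruleset order (deterministic)."""
    if not ruleset:
        raise ValidationError("ruleset must be non-empty")
    entries = [
        evaluate_rule(record.lifestyle.get(rule.behaviour_id), rule, age=record.age)
        for rule in ruleset
    ]
    return AdviceReport(entries=entries)


def _parse_rule(index: int, doc: dict) -> LifestyleRule:
    if not isinstance(doc, dict):
        raise ConfigurationError(f"rule {index}: expected a mapping")
    for field in ("behaviour_id", "comparator", "units"):
        if field not in doc:
            raise ConfigurationError(f"rule {index}: missing field {field!r}")
    for field in ("encouragement_text", "advice_text"):
        if field not in doc or not isinstance(doc[field], str):
            raise ConfigurationError(f"rule {index}: missing field {field!r}")
    bands = tuple(
        AgeBand(float(b["min_age"]), float(b["max_age"]), float(b["level"]))
        for b in doc.get("age_bands", [])
    )
    level = doc.get("recommended_level")
    if level is None and not bands:
        raise ConfigurationError(f"rule {index}: missing field 'recommended_level'")
    try:
        return LifestyleRule(
            behaviour_id=str(doc["behaviour_id"]),
            comparator=str(doc["comparator"]),
            recommended_level=None if level is None else float(level),
            units=str(doc["units"]),
            encouragement_text=doc["encouragement_text"],
            advice_text=doc["advice_text"],
            label=doc.get("label"),
            age_bands=bands,
        )
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"rule {index}: {exc}") from None


def load_ruleset(source) -> list[LifestyleRule]:
    """Load and validate a ruleset from a YAML path, stream or parsed dict."""
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    elif isinstance(source, dict):
        doc = source
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ConfigurationError("ruleset document must contain a top-level 'rules' list")
    rules = [_parse_rule(i, r) for i, r in enumerate(doc["rules"])]
    seen: set[str] = set()
    for rule in rules:
        if rule.behaviour_id in seen:
            raise ConfigurationError(f"duplicate behaviour_id {rule.behaviour_id!r}")
        seen.add(rule.behaviour_id)
    if not rules:
        raise ConfigurationError("ruleset must contain at least one rule")
    return rules


def load_default_ruleset() -> list[LifestyleRule]:
    """Packaged default ruleset (editable placeholder levels)."""
    with resources.files("childcheck.data").joinpath("default_ruleset.yaml").open("r") as fh:
        return load_ruleset(fh)
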