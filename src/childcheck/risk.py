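"""Logistic comorbidity risk models, cut-off calibration and performance.

Two rules calibrate the Low/Medium/High strata the way the original
decision-support algorithms were calibrated on their derivation cohorts:

* the **High** cut-off is the empirical (1 - prevalence) quantile of the
  risk scores among overweight children, so that the proportion of
  overweight children whose score strictly exceeds the cut-off equals the
  outcome prevalence as closely as the discrete sample allows (never
  exceeding it);
* the **Low** cut-off maximises the negative predictive value (NPV) of the
  rule "score <= cut-off -> predicted negative", breaking ties towards the
  cut-off that reassures the most children.

Model selection is forward stepwise: a candidate covariate is retained only
if it is significant (Wald p < alpha) and strictly improves the in-sample
AUC of the receiver operating characteristic; among qualifying candidates
the one with the largest AUC gain enters first.

Risk scores throughout are predicted probabilities. Probabilities and
linear predictors are monotonically equivalent, so stratification is
unaffected by the choice; probabilities are used for interpretability.
"""
from __future__ import annotations

import dataclasses
import enum
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import SeparationError, ValidationError

logger = logging.getLogger(__name__)


class RiskLevel(str, enum.Enum):
    Low = "Low"
    Medium = "Medium"
    High = "High"


@dataclasses.dataclass
class RiskModel:
    """A fitted logistic risk score: p = logistic(intercept + sum(beta * x))."""

    outcome_name: str
    intercept: float
    coefficients: dict[str, float] = dataclasses.field(default_factory=dict)
    p_values: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValidationError("covariate ids must be unique")

    def predict(self, covariates: Mapping[str, float]) -> float:
        return predict_risk(self, covariates)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.coefficients if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing covariate column(s): {missing}")
        eta = np.full(len(frame), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            eta += beta * frame[name].to_numpy(float)
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "p_values": dict(self.p_values),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RiskModel":
        return cls(
            outcome_name=doc["outcome_name"],
            intercept=float(doc["intercept"]),
            coefficients={k: float(v) for k, v in doc["coefficients"].items()},
            p_values={k: float(v) for k, v in doc.get("p_values", {}).items()},
        )


@dataclasses.dataclass(frozen=True)
class RiskStrata:
    """Cut-off pair: score <= low -> Low; low < score <= high -> Medium; else High."""

    low_cutoff: float
    high_cutoff: float

    def __post_init__(self) -> None:
        if self.low_cutoff > self.high_cutoff:
            raise ValidationError("low_cutoff must be <= high_cutoff")

    def classify(self, score: float) -> RiskLevel:
        if score <= self.low_cutoff:
            return RiskLevel.Low
        if score <= self.high_cutoff:
            return RiskLevel.Medium
        return RiskLevel.High


def predict_risk(model: RiskModel, covariates: Mapping[str, float]) -> float:
    """Predicted outcome probability for one covariate map, strictly in (0, 1)."""
    eta = model.intercept
    for name, beta in model.coefficients.items():
        if name not in covariates:
            raise ValidationError(f"missing covariate: {name!r}")
        eta += beta * float(covariates[name])
    return float(expit(eta))


def _check_binary_outcome(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValidationError("outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValidationError("outcome must contain both classes")
    return y


def _find_separating(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    # a covariate whose class-conditional supports do not overlap separates
    out = []
    for col in X.columns:
        v = X[col].to_numpy(float)
        a, b = v[y == 1], v[y == 0]
        if a.min() >= b.max() or b.min() >= a.max():
            out.append(col)
    return out


def fit_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
) -> RiskModel:
    """Maximum-likelihood logistic regression with Wald two-sided p-values.

    Raises :class:`SeparationError` naming the offending covariate(s) when
    the fit is perfectly (quasi-)separated, and :class:`ValidationError`
    when the outcome has a single class or n <= #covariates + 1.
    """
    y = _check_binary_outcome(cohort[outcome].to_numpy())
    covariates = list(covariates)
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValidationError(f"missing covariate column(s): {missing}")
    if len(cohort) <= len(covariates) + 1:
        raise ValidationError("need n > number of covariates + 1")
    X = sm.add_constant(cohort[covariates].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        offenders = _find_separating(cohort[covariates].astype(float), y) or covariates
        raise SeparationError(offenders) from None
    # enormous standard errors flag quasi-separation the solver survived
    if covariates and np.any(np.asarray(res.bse)[1:] > 1e3):
        offenders = _find_separating(cohort[covariates].astype(float), y)
        if offenders:
            raise SeparationError(offenders)
    params = np.asarray(res.params, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    return RiskModel(
        outcome_name=outcome,
        intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(covariates, params[1:])},
        p_values={c: float(p) for c, p in zip(covariates, pvals[1:])},
    )


def auc(scores: Iterable[float], outcomes: Iterable[float]) -> float:
    """Area under the ROC curve (Mann–Whitney pair statistic)."""
    y = _check_binary_outcome(np.asarray(list(outcomes)))
    s = np.asarray(list(scores), dtype=float)
    if len(s) != len(y):
        raise ValidationError("scores and outcomes must have equal length")
    return float(roc_auc_score(y, s))


@dataclasses.dataclass(frozen=True)
class StepRecord:
    """One forward-selection round: the covariate added, its p, the new AUC."""

    covariate: str
    p_value: float
    auc: float
    auc_gain: float


@dataclasses.dataclass
class StepwiseResult:
    model: RiskModel
    trace: list[StepRecord]


def stepwise_auc_select(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
    min_auc_gain: float = 0.0,
) -> StepwiseResult:
    """Forward stepwise selection gated on significance and AUC improvement.

    Each round tentatively adds every remaining candidate to the current
    model; among those with Wald p < ``alpha`` and in-sample AUC exceeding
    the current model's by more than ``min_auc_gain`` (default: any strict
    improvement), the largest AUC gain wins. Stops when no candidate
    qualifies. Candidates that cause perfect separation are dropped with a
    logged warning.
    """
    y = _check_binary_outcome(cohort[outcome].to_numpy())
    selected: list[str] = []
    current = fit_logistic(cohort, outcome)  # intercept-only
    current_auc = 0.5  # constant score: every case-control pair ties
    pool = list(dict.fromkeys(candidates))
    trace: list[StepRecord] = []
    while pool:
        best: Optional[tuple[float, str, RiskModel, float]] = None
        for cand in list(pool):
            try:
                trial = fit_logistic(cohort, outcome, selected + [cand])
            except SeparationError:
                logger.warning("dropping covariate %r: perfect separation", cand)
                pool.remove(cand)
                continue
            p = trial.p_values[cand]
            trial_auc = auc(trial.predict_frame(cohort), y)
            if p < alpha and trial_auc > current_auc + min_auc_gain:
                if best is None or trial_auc > best[0]:
                    best = (trial_auc, cand, trial, p)
        if best is None:
            break
        trial_auc, cand, current, p = best
        trace.append(
            StepRecord(covariate=cand, p_value=p, auc=trial_auc, auc_gain=trial_auc - current_auc)
        )
        current_auc = trial_auc
        selected.append(cand)
        pool.remove(cand)
    return StepwiseResult(model=current, trace=trace)


def calibrate_high_cutoff(scores_overweight: Iterable[float], prevalence: float) -> float:
    """High-risk cut-off from the outcome prevalence among overweight children.

    Returns the empirical (1 - prevalence) quantile: the fraction of scores
    *strictly* exceeding the returned cut-off matches ``prevalence`` as
    closely as the discrete sample allows without exceeding it.
    """
    s = np.sort(np.asarray(list(scores_overweight), dtype=float))
    if s.size == 0:
        raise ValidationError("scores must be non-empty")
    if not (0.0 <= prevalence <= 1.0):
        raise ValidationError("prevalence must lie in [0, 1]")
    target = prevalence * s.size
    # exceed-count is non-increasing in the cut-off; pick the smallest
    # observed value whose exceed-count does not overshoot the target
    for c in np.unique(s):
        if np.count_nonzero(s > c) <= target:
            return float(c)
    return float(s[-1])  # unreachable: the max always has exceed-count 0


def calibrate_low_cutoff(scores: Iterable[float], outcomes: Iterable[float]) -> float:
    """Low-risk cut-off maximising NPV of "score <= cut-off -> negative".

    Candidates are the distinct observed scores plus a sentinel below the
    minimum (NPV is a step function changing only at observed scores). Ties
    in NPV are broken towards the cut-off classifying the most children as
    low risk; with an outcome-free sample NPV is 1 everywhere and the
    maximal cut-off is returned.
    """
    y = np.asarray(list(outcomes), dtype=float)
    if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
        raise ValidationError("outcome must be coded 0/1")
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValidationError("scores must be non-empty")
    if len(s) != len(y):
        raise ValidationError("scores and outcomes must have equal length")
    candidates = np.concatenate(([s.min() - 1.0], np.unique(s)))
    best_cut, best_npv, best_n_low = None, -1.0, -1
    for c in candidates:
        mask = s <= c
        n_low = int(mask.sum())
        if n_low == 0:
            continue  # NPV undefined, never optimal
        npv = float(np.mean(y[mask] == 0))
        if npv > best_npv or (npv == best_npv and n_low > best_n_low):
            best_cut, best_npv, best_n_low = float(c), npv, n_low
    assert best_cut is not None
    return best_cut


def calibrate_strata(
    scores: Iterable[float],
    outcomes: Iterable[float],
    prevalence: Optional[float] = None,
) -> RiskStrata:
    """Calibrate both cut-offs on one derivation sample.

    ``prevalence`` defaults to the realised outcome prevalence in the
    sample. If the NPV-optimal Low cut-off lands above the High cut-off the
    pair is clamped to equality with a logged warning.
    """
    s = np.asarray(list(scores), dtype=float)
    y = _check_binary_outcome(np.asarray(list(outcomes)))
    if prevalence is None:
        prevalence = float(np.mean(y))
    high = calibrate_high_cutoff(s, prevalence)
    low = calibrate_low_cutoff(s, y)
    if low > high:
        logger.warning(
            "low cut-off %.6g exceeds high cut-off %.6g; clamping to equality", low, high
        )
        low = high
    return RiskStrata(low_cutoff=low, high_cutoff=high)


def stratify(score: float, strata: RiskStrata) -> RiskLevel:
    """Classify one risk score into Low/Medium/High."""
    return strata.classify(score)


@dataclasses.dataclass(frozen=True)
class PerformanceReport:
    """Confusion-matrix metrics for one stratification convention.

    ``high-vs-outcome``: positive prediction = High stratum, condition =
    outcome present. ``low-vs-no-outcome``: positive prediction = Low
    stratum, condition = outcome absent. Metrics with a zero denominator are
    reported as None, never 0.
    """

    convention: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    auc: float
    counts: dict[str, int]


_CONVENTIONS = ("high-vs-outcome", "low-vs-no-outcome")


def performance_report(
    scores: Iterable[float],
    outcomes: Iterable[float],
    strata: RiskStrata,
    convention: str = "high-vs-outcome",
) -> PerformanceReport:
    """Sensitivity/specificity/PPV/NPV (plus AUC) for a stratified score."""
    if convention not in _CONVENTIONS:
        raise ValidationError(f"convention must be one of {_CONVENTIONS}")
    y = _check_binary_outcome(np.asarray(list(outcomes)))
    s = np.asarray(list(scores), dtype=float)
    levels = np.array([strata.classify(v).value for v in s])
    if convention == "high-vs-outcome":
        predicted = levels == RiskLevel.High.value
        condition = y == 1
    else:
        predicted = levels == RiskLevel.Low.value
        condition = y == 0
    tp = int(np.sum(predicted & condition))
    fp = int(np.sum(predicted & ~condition))
    fn = int(np.sum(~predicted & condition))
    tn = int(np.sum(~predicted & ~condition))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return PerformanceReport(
        convention=convention,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        auc=auc(s, y),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def save_risk_document(
    path: str | Path,
    model: RiskModel,
    strata: Optional[RiskStrata] = None,
    metadata: Optional[Mapping] = None,
) -> None:
    """Serialise a fitted model (+ strata, calibration metadata) to JSON.

    The document round-trips exactly: floats are written with full repr
    precision.
    """
    doc: dict = {"model": model.to_dict()}
    if strata is not None:
        doc["strata"] = {"low_cutoff": strata.low_cutoff, "high_cutoff": strata.high_cutoff}
    if metadata is not None:
        doc["metadata"] = dict(metadata)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_risk_document(
    path: str | Path,
) -> tuple[RiskModel, Optional[RiskStrata], dict]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    model = RiskModel.from_dict(doc["model"])
    strata = None
    if "strata" in doc:
        strata = RiskStrata(
            low_cutoff=float(doc["strata"]["low_cutoff"]),
            high_cutoff=float(doc["strata"]["high_cutoff"]),
        )
    return model, strata, doc.get("metadata", {})
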