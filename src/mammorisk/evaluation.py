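"""Cohort-level evaluation of the system as a binary classifier.

Risk scores (Global or Corrected Global) are binarized at an operating
point (default 60, the "potential case" boundary, so dubious cases count
as negative) and summarized with the standard confusion-matrix metrics —
sensitivity, specificity, false-negative and false-positive rates — plus
the Matthews correlation coefficient and a rank-based (Mann-Whitney) ROC
AUC with half-credit for ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .aggregation import (
    DEFAULT_BASE_WEIGHTS,
    DEFAULT_CORRECTION,
    DEFAULT_THRESHOLDS,
    AggregationWeights,
    CorrectionParams,
    StateThresholds,
)
from .datamodel import Cohort
from .fuzzy import ExpertSystemSpec
from .pipeline import assess_patient
from .statistical import ClassifierModel

__all__ = [
    "EvaluationReport",
    "EvaluationError",
    "binarize",
    "confusion_metrics",
    "mcc",
    "auc",
    "evaluate_cohort",
]

POSITIVE = "cancer"
NEGATIVE = "non-cancer"


class EvaluationError(ValueError):
    """Evaluation inputs are unusable (e.g. single-class truth)."""


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion-derived metrics (in %) and AUC for one risk variant."""

    variant: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fnr: float
    fpr: float
    mcc: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "threshold": self.threshold,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "false_negative_rate_pct": self.fnr,
            "false_positive_rate_pct": self.fpr,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def binarize(risks: Sequence[float], threshold: float = 60.0) -> list[str]:
    """Predicted cancer iff risk >= threshold."""
    out = []
    for r in risks:
        if not 0 <= r <= 100:
            raise EvaluationError(f"risk {r} outside [0, 100]")
        out.append(POSITIVE if r >= threshold else NEGATIVE)
    return out


def _counts(predicted: Sequence[str], truth: Sequence[str]) -> tuple[int, int, int, int]:
    if len(predicted) != len(truth):
        raise EvaluationError("predicted and truth must have equal length")
    if set(truth) != {POSITIVE, NEGATIVE}:
        raise EvaluationError(f"truth must contain both classes, got {sorted(set(truth))}")
    tp = sum(p == POSITIVE and t == POSITIVE for p, t in zip(predicted, truth))
    fp = sum(p == POSITIVE and t == NEGATIVE for p, t in zip(predicted, truth))
    tn = sum(p == NEGATIVE and t == NEGATIVE for p, t in zip(predicted, truth))
    fn = sum(p == NEGATIVE and t == POSITIVE for p, t in zip(predicted, truth))
    return tp, fp, tn, fn


def confusion_metrics(predicted: Sequence[str], truth: Sequence[str]) -> dict:
    """Sensitivity/specificity and their complements, in percent, plus counts."""
    tp, fp, tn, fn = _counts(predicted, truth)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "false_negative_rate_pct": 100.0 - sens,
        "false_positive_rate_pct": 100.0 - spec,
    }


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 (with a warning) when a marginal
    is empty and the denominator vanishes."""
    den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if den == 0:
        warnings.warn("MCC denominator is zero; returning 0 by convention", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / den


def auc(scores: Sequence[float], truth: Sequence[int] | Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for ties.

    ``truth`` may be 0/1 integers or cancer / non-cancer labels.
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    if t.dtype.kind in "UO":
        t = (t == POSITIVE).astype(int)
    t = t.astype(int)
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present in truth")
    ranks = rankdata(scores)  # average ranks handle ties with half credit
    r_pos = ranks[t == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _report(variant: str, scores: Sequence[float], truth: Sequence[str], threshold: float) -> EvaluationReport:
    metrics = confusion_metrics(binarize(scores, threshold), truth)
    return EvaluationReport(
        variant=variant,
        threshold=threshold,
        tp=metrics["TP"],
        fp=metrics["FP"],
        tn=metrics["TN"],
        fn=metrics["FN"],
        sensitivity=metrics["sensitivity_pct"],
        specificity=metrics["specificity_pct"],
        fnr=metrics["false_negative_rate_pct"],
        fpr=metrics["false_positive_rate_pct"],
        mcc=mcc(metrics["TP"], metrics["FP"], metrics["TN"], metrics["FN"]),
        auc=auc(scores, truth),
    )


def evaluate_cohort(
    cohort: Cohort,
    specs: Mapping[str, ExpertSystemSpec],
    model: ClassifierModel,
    threshold: float = 60.0,
    *,
    base_weights: AggregationWeights = DEFAULT_BASE_WEIGHTS,
    correction: CorrectionParams = DEFAULT_CORRECTION,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Run the full pipeline per patient and score both risk variants.

    Returns ``(global_report, corrected_report)``; requires a fully labeled
    cohort with both outcomes represented.
    """
    truth, rg_scores, rgc_scores = [], [], []
    for record in cohort:
        if record.label is None:
            raise EvaluationError(f"record {record.patient_id!r} is unlabeled")
        profile = assess_patient(
            record,
            specs,
            model,
            base_weights=base_weights,
            correction=correction,
            thresholds=thresholds,
        )
        truth.append(record.label)
        rg_scores.append(profile.rg)
        rgc_scores.append(profile.rg_corrected)
    return (
        _report("global", rg_scores, truth, threshold),
        _report("corrected_global", rgc_scores, truth, threshold),
    )
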