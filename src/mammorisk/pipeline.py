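"""End-to-end per-patient assessment: symbolic + statistical -> profile.

Wires the stages together: the three fuzzy expert systems (Symbolic Risks),
the bagged-trees classifier (Statistical Risk), weight redistribution,
Global Risk aggregation, BI-RADS correction and state classification.
Component risks can be overridden (e.g. when a medical team wants to replay
the arithmetic on externally supplied risks), which also decouples the
aggregation from any particular rule base.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .aggregation import (
    DEFAULT_BASE_WEIGHTS,
    DEFAULT_CORRECTION,
    DEFAULT_THRESHOLDS,
    RECOMMENDATIONS,
    AggregationError,
    AggregationWeights,
    CorrectionParams,
    RiskProfile,
    StateThresholds,
    classify_state,
    corrected_global_risk,
    correction_factor,
    global_risk,
    redistribute_weights,
)
from .datamodel import PatientRecord
from .fuzzy import ExpertSystemSpec
from .statistical import ClassifierModel, predict_statistical_risk
from .symbolic import SymbolicRiskSet, assess_all

__all__ = ["assess_patient"]


def assess_patient(
    record: PatientRecord,
    specs: Mapping[str, ExpertSystemSpec],
    model: Optional[ClassifierModel] = None,
    *,
    rs_override: Optional[float] = None,
    risks_override: Optional[SymbolicRiskSet] = None,
    base_weights: AggregationWeights = DEFAULT_BASE_WEIGHTS,
    correction: CorrectionParams = DEFAULT_CORRECTION,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> RiskProfile:
    """Run Stages 1-4 for one validated record and return its RiskProfile.

    Either ``model`` or ``rs_override`` must supply the Statistical Risk.
    A findings-free mammogram (all three Symbolic Risks NULL) is reported
    as zero risk in the healthy state with an explicit "no findings" note
    rather than an inference.
    """
    notes: list[str] = []
    risks = risks_override if risks_override is not None else assess_all(record, specs)

    if rs_override is not None:
        rs = float(rs_override)
    elif model is not None:
        rs = predict_statistical_risk(model, record)
    else:
        raise AggregationError("no Statistical Risk source: supply a model or rs_override")

    if all(risks.null_flags):
        notes.append("no findings: no mass, calcifications, asymmetry or distortion")
        weights = base_weights  # nothing to redistribute; RG fixed at 0
        rg, fp, rg_c = 0.0, 1.0, 0.0
    else:
        weights = redistribute_weights(base_weights, risks.null_flags)
        rg = global_risk(risks, weights, rs)
        correction.branch(record.birads)  # reject incomplete studies up front
        if rg == 0.0:
            notes.append("Global Risk is 0: BI-RADS correction skipped")
            fp = 1.0
            rg_c = 0.0
        else:
            fp = correction_factor(record.birads, rg, correction)
            rg_c = corrected_global_risk(rg, fp)

    state = classify_state(rg_c, thresholds)
    if rg_c >= 100.0:
        notes.append("maximum alert: Corrected Global Risk at its ceiling")
    return RiskProfile(
        patient_id=record.patient_id,
        risks=risks,
        weights=weights,
        rs=rs,
        rg=rg,
        fp=fp,
        rg_corrected=rg_c,
        state=state,
        recommendation=RECOMMENDATIONS[state],
        notes=tuple(notes),
    )
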