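"""Risk aggregation: Global Risk, BI-RADS correction and warning states.

Global Risk
-----------
The Symbolic Risks and the Statistical Risk are aggregated as

    RG = clamp( (w1*R1 + w2*R2 + w3*R3) * log10(Rs), 0, 100 )

i.e. the weighted sum of the per-finding symbolic risks, multiplied by the
decimal logarithm of the statistical risk (the log term amplifies the risk
when the patient resembles the cancer cases the classifier was trained on).
Rs is floored at 1 so the log term is never negative — risk cannot be
*reduced* below zero by a dissimilar statistical pattern.  When a finding
group is absent its risk is NULL and its weight is redistributed equally
among the remaining findings.

BI-RADS correction
------------------
The Corrected Global Risk RG' = RG * Fp rescales RG toward the standard
medical reading of the assigned BI-RADS category, with f(RG) = 10/(RG+10)
and Fc = 100/RG:

* categories 1-2 (attenuate):  Fp = 1 / (k + f(RG)),  k = -level + 3.5;
* categories 3-4C (amplify):   Fp = t + f(RG) capped at Fc,  t = level - 1.5;
* categories 5-6 (saturate):   Fp = Fc, driving RG' to 100.

Numeric levels for the sub-categories follow their ordinal position
(1, 2, 3, 4A, 4B, 4C -> 1..6); category 0 denotes an incomplete study and
has no defined correction.  RG' is capped at 100.

Warning states on the Corrected Global Risk: healthy (< 40), dubious
(40 <= RG' < 60), potential cancer case (>= 60), each with a standard
recommendation string.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .symbolic import SymbolicRiskSet

__all__ = [
    "AggregationWeights",
    "CorrectionParams",
    "StateThresholds",
    "RiskProfile",
    "AggregationError",
    "IncompleteStudyError",
    "DEFAULT_BASE_WEIGHTS",
    "DEFAULT_CORRECTION",
    "DEFAULT_THRESHOLDS",
    "RECOMMENDATIONS",
    "redistribute_weights",
    "global_risk",
    "correction_factor",
    "corrected_global_risk",
    "classify_state",
]


class AggregationError(ValueError):
    """Aggregation cannot proceed (e.g. all three risks are NULL)."""


class IncompleteStudyError(ValueError):
    """BI-RADS 0 marks an incomplete study; no correction is defined."""


@dataclass(frozen=True)
class AggregationWeights:
    """Nonnegative weights over (R1, R2, R3) summing to one."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise AggregationError(f"weights must be nonnegative: {self.as_tuple()}")
        if abs(sum(self.as_tuple()) - 1.0) > 1e-9:
            raise AggregationError(f"weights must sum to 1: {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


DEFAULT_BASE_WEIGHTS = AggregationWeights(1 / 3, 1 / 3, 1 / 3)


def redistribute_weights(
    base: AggregationWeights, null_flags: Sequence[bool]
) -> AggregationWeights:
    """Zero the weights of NULL risks and share their mass equally among the
    surviving ones (equitable redistribution)."""
    if len(null_flags) != 3:
        raise AggregationError("null_flags must have length 3")
    alive = [i for i, is_null in enumerate(null_flags) if not is_null]
    if not alive:
        raise AggregationError("no findings to aggregate: all three risks are NULL")
    base_w = base.as_tuple()
    freed = sum(base_w[i] for i in range(3) if i not in alive)
    share = freed / len(alive)
    out = [0.0, 0.0, 0.0]
    for i in alive:
        out[i] = base_w[i] + share
    return AggregationWeights(*out)


def global_risk(
    risks: SymbolicRiskSet | Sequence[Optional[float]],
    weights: AggregationWeights,
    rs: float,
) -> float:
    """Aggregate the Symbolic Risks and the Statistical Risk into the Global
    Risk, clamped to [0, 100].  NULL risks contribute zero (their weight must
    already be zero via :func:`redistribute_weights`)."""
    if isinstance(risks, SymbolicRiskSet):
        r = (risks.r1, risks.r2, risks.r3)
    else:
        r = tuple(risks)
    if not 0 <= rs <= 100:
        raise AggregationError(f"Statistical Risk {rs} outside [0, 100]")
    weighted = sum(w * (ri or 0.0) for w, ri in zip(weights.as_tuple(), r))
    rg = weighted * math.log10(max(rs, 1.0))
    return min(max(rg, 0.0), 100.0)


#: ordinal numeric level of each BI-RADS category usable in the correction
DEFAULT_BIRADS_LEVELS: dict[str, float] = {"1": 1, "2": 2, "3": 3, "4A": 4, "4B": 5, "4C": 6, "5": 7, "6": 8}

_ATTENUATE = frozenset({"1", "2"})
_AMPLIFY = frozenset({"3", "4A", "4B", "4C"})
_SATURATE = frozenset({"5", "6"})


@dataclass(frozen=True)
class CorrectionParams:
    """BI-RADS-category to correction-branch map with its numeric levels.

    ``k = -level + 3.5`` on the attenuate branch; ``t = level - 1.5`` on the
    amplify branch.  The level map is configurable (the sub-category numbers
    are a convention, not a standard)."""

    levels: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BIRADS_LEVELS))

    def branch(self, birads: str) -> str:
        if birads in _ATTENUATE:
            return "attenuate"
        if birads in _AMPLIFY:
            return "amplify"
        if birads in _SATURATE:
            return "saturate"
        raise IncompleteStudyError(
            f"BI-RADS {birads!r}: incomplete study, no correction defined"
        )


DEFAULT_CORRECTION = CorrectionParams()


def correction_factor(
    birads: str, rg: float, params: CorrectionParams = DEFAULT_CORRECTION
) -> float:
    """The weighting factor Fp for the given BI-RADS category and Global Risk.

    For RG = 0 the correction is skipped (Fp = 1) with a warning: both the
    amplify cap Fc = 100/RG and the saturate branch are undefined at zero
    risk, and there is nothing to rescale.
    """
    branch = params.branch(birads)
    if rg == 0:
        warnings.warn("Global Risk is 0: correction skipped (Fp = 1)", stacklevel=2)
        return 1.0
    if not 0 < rg <= 100:
        raise AggregationError(f"Global Risk {rg} outside [0, 100]")
    f_rg = 10.0 / (rg + 10.0)
    level = params.levels[birads]
    if branch == "attenuate":
        k = -level + 3.5
        return 1.0 / (k + f_rg)
    if branch == "amplify":
        t = level - 1.5
        fc = 100.0 / rg
        return min(t + f_rg, fc)
    return 100.0 / rg  # saturate


def corrected_global_risk(rg: float, fp: float) -> float:
    """RG' = RG * Fp, capped at 100."""
    if fp <= 0:
        raise AggregationError(f"correction factor must be positive, got {fp}")
    return min(rg * fp, 100.0)


@dataclass(frozen=True)
class StateThresholds:
    """Half-open state boundaries on the Corrected Global Risk scale."""

    dubious: float = 40.0
    potential: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.dubious < self.potential <= 100:
            raise AggregationError(
                f"thresholds must satisfy 0 < dubious < potential <= 100, "
                f"got ({self.dubious}, {self.potential})"
            )


DEFAULT_THRESHOLDS = StateThresholds()

RECOMMENDATIONS = {
    "healthy": "Refer the patient for routine review.",
    "dubious": (
        "Reconsider the patient's case; consider performing other tests and "
        "summoning the patient for a new visit."
    ),
    "potential": "Perform confirmatory tests.",
}


def classify_state(rg_corrected: float, thresholds: StateThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map the Corrected Global Risk to healthy / dubious / potential."""
    if not 0 <= rg_corrected <= 100:
        raise AggregationError(f"risk {rg_corrected} outside [0, 100]")
    if rg_corrected < thresholds.dubious:
        return "healthy"
    if rg_corrected < thresholds.potential:
        return "dubious"
    return "potential"


@dataclass(frozen=True)
class RiskProfile:
    """All per-patient outputs of the risk pipeline, for transparent reports."""

    patient_id: str
    risks: SymbolicRiskSet
    weights: AggregationWeights
    rs: float
    rg: float
    fp: float
    rg_corrected: float
    state: str
    recommendation: str
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "R1": self.risks.r1,
            "R2": self.risks.r2,
            "R3": self.risks.r3,
            "weights": list(self.weights.as_tuple()),
            "Rs": self.rs,
            "RG": self.rg,
            "Fp": self.fp,
            "RG_corrected": self.rg_corrected,
            "state": self.state,
            "recommendation": self.recommendation,
            "notes": list(self.notes),
        }
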