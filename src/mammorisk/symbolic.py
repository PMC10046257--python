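"""The three concurrent fuzzy expert systems producing the Symbolic Risks.

* ``R1`` — masses (shape, margins, density);
* ``R2`` — calcifications (type, shape, distribution);
* ``R3`` — asymmetries & architectural distortion (presence and type of each).

A risk is NULL (``None``) exactly when its finding group is absent on the
mammogram — for R3, only when *both* asymmetry and distortion are absent.
Absence is decided by the radiologist's present/absent flags, never by a
computed zero: a present but benign-looking finding legitimately yields a
small non-zero centroid.

Shipped rule bases
------------------
The default knowledge bases are generated from documented ordinal suspicion
orderings of the BI-RADS lexicon (e.g. mass shape none < oval ~ round <
lobulated < irregular; margins circumscribed < obscured < micro-lobulated <
indistinct < spiculated; calcification shapes typically-benign < amorphous /
coarse heterogeneous < fine pleomorphic / fine linear < fine linear
branching).  Each categorical input combination gets exactly one rule whose
consequent label is the suspicion-score sum mapped onto the five ordered
risk labels.  This makes every rule base *total* (every combination fires)
and *ordinal-monotone* (raising any single antecedent to a more suspicious
category never lowers the risk).  The bases live in editable YAML files
under :mod:`mammorisk.rulebases` so that a medical team can substitute its
own knowledge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .datamodel import (
    ASYMMETRY_TYPE,
    CALC_DISTRIBUTION,
    CALC_SHAPE,
    CALC_TYPE,
    DISTORTION_TYPE,
    MASS_DENSITY,
    MASS_MARGINS,
    MASS_SHAPE,
    PatientRecord,
)
from .fuzzy import (
    ExpertSystemSpec,
    FuzzyRule,
    NoRuleFiredError,
    default_consequents,
    infer,
    load_expert_system,
)

__all__ = [
    "SymbolicRiskSet",
    "RuleBaseConfigurationError",
    "SUSPICION_ORDER",
    "build_masses_spec",
    "build_calcifications_spec",
    "build_asymmetry_distortion_spec",
    "default_specs",
    "assess_masses",
    "assess_calcifications",
    "assess_asymmetry_distortion",
    "assess_all",
]


class RuleBaseConfigurationError(RuntimeError):
    """A present finding hit an input combination not covered by any rule."""


@dataclass(frozen=True)
class SymbolicRiskSet:
    """Per-finding-group risks in [0, 100]; ``None`` means the group is absent."""

    r1: Optional[float]
    r2: Optional[float]
    r3: Optional[float]

    @property
    def null_flags(self) -> tuple[bool, bool, bool]:
        return (self.r1 is None, self.r2 is None, self.r3 is None)


#: ordinal suspicion scores per antecedent category (higher = more suspicious).
#: Ties encode "equally suspicious" categories; density acts as a minor modifier.
SUSPICION_ORDER: dict[str, dict[str, int]] = {
    "mass_shape": {"none": 0, "oval": 1, "round": 1, "lobulated": 2, "irregular": 3},
    "mass_margins": {
        "none": 0,
        "circumscribed": 1,
        "obscured": 2,
        "micro-lobulated": 3,
        "indistinct": 4,
        "spiculated": 5,
    },
    "mass_density": {"none": 0, "low density": 1, "equal density": 1, "high density": 2},
    "calc_type": {"none": 0, "primary": 1, "associated": 1},
    "calc_shape": {
        "none": 0,
        "skin": 1,
        "vascular": 1,
        "coarse": 1,
        "large rod-like": 1,
        "round": 1,
        "rim": 1,
        "dystrophic": 1,
        "milk of calcium": 1,
        "suture": 1,
        "amorphous": 3,
        "coarse heterogeneous": 3,
        "fine pleomorphic": 4,
        "fine linear": 4,
        "fine linear branching": 5,
    },
    "calc_distribution": {
        "none": 0,
        "diffuse": 1,
        "regional": 2,
        "grouped": 3,
        "linear": 4,
        "segmental": 5,
    },
    "asymmetry_type": {"none": 0, "missing": 1, "focal": 2, "developing": 3},
    "distortion_type": {"none": 0, "primary": 1, "associated": 2},
    "presence": {"absent": 0, "present": 1},
}


def _score_to_label(score: int, max_score: int, labels: tuple[str, ...]) -> str:
    # proportional mapping of the summed ordinal score onto the ordered labels
    idx = int(score * (len(labels) - 1) / max_score + 0.5)
    return labels[idx]


def _build_scored_spec(
    name: str,
    output_name: str,
    variables: dict[str, tuple[str, ...]],
    scores: dict[str, dict[str, int]],
) -> ExpertSystemSpec:
    consequents = default_consequents()
    labels = tuple(consequents)
    max_score = sum(max(s.values()) for s in scores.values())
    rules = []
    names = list(variables)
    for combo in itertools.product(*(variables[v] for v in names)):
        total = sum(scores[v][c] for v, c in zip(names, combo))
        rules.append(
            FuzzyRule(
                antecedent=tuple(zip(names, combo)),
                consequent=_score_to_label(total, max_score, labels),
            )
        )
    return ExpertSystemSpec(
        name=name,
        variables=variables,
        output_name=output_name,
        consequents=consequents,
        rules=rules,
    )


def build_masses_spec() -> ExpertSystemSpec:
    """Expert system 1 — masses; antecedents shape, margins, density."""
    return _build_scored_spec(
        "masses",
        "R1",
        {
            "shape": MASS_SHAPE,
            "margins": MASS_MARGINS,
            "density": MASS_DENSITY,
        },
        {
            "shape": SUSPICION_ORDER["mass_shape"],
            "margins": SUSPICION_ORDER["mass_margins"],
            "density": SUSPICION_ORDER["mass_density"],
        },
    )


def build_calcifications_spec() -> ExpertSystemSpec:
    """Expert system 2 — calcifications; antecedents type, shape, distribution."""
    return _build_scored_spec(
        "calcifications",
        "R2",
        {
            "type": CALC_TYPE,
            "shape": CALC_SHAPE,
            "distribution": CALC_DISTRIBUTION,
        },
        {
            "type": SUSPICION_ORDER["calc_type"],
            "shape": SUSPICION_ORDER["calc_shape"],
            "distribution": SUSPICION_ORDER["calc_distribution"],
        },
    )


def build_asymmetry_distortion_spec() -> ExpertSystemSpec:
    """Expert system 3 — asymmetries & architectural distortion.

    Four antecedents: the present/absent flag and type of each sub-group
    (absent sub-groups enter with category "none").
    """
    return _build_scored_spec(
        "asymmetry_distortion",
        "R3",
        {
            "asymmetry": ("absent", "present"),
            "asymmetry_type": ASYMMETRY_TYPE,
            "distortion": ("absent", "present"),
            "distortion_type": DISTORTION_TYPE,
        },
        {
            "asymmetry": SUSPICION_ORDER["presence"],
            "asymmetry_type": SUSPICION_ORDER["asymmetry_type"],
            "distortion": SUSPICION_ORDER["presence"],
            "distortion_type": SUSPICION_ORDER["distortion_type"],
        },
    )


_BUNDLED = {
    "masses": "masses.yaml",
    "calcifications": "calcifications.yaml",
    "asymmetry_distortion": "asymmetry_distortion.yaml",
}


def default_specs(directory: Optional[str | Path] = None) -> dict[str, ExpertSystemSpec]:
    """Load the three rule bases, from ``directory`` if given, else the
    bundled YAML files."""
    specs = {}
    if directory is not None:
        for key, filename in _BUNDLED.items():
            specs[key] = load_expert_system(Path(directory) / filename)
    else:
        pkg = resources.files("mammorisk.rulebases")
        for key, filename in _BUNDLED.items():
            with resources.as_file(pkg / filename) as path:
                specs[key] = load_expert_system(path)
    return specs


def _infer_or_raise(spec: ExpertSystemSpec, inputs: Mapping[str, str]) -> float:
    try:
        return infer(spec, inputs)
    except NoRuleFiredError:
        raise RuleBaseConfigurationError(
            f"rule base {spec.name!r} does not cover input combination {dict(inputs)}"
        ) from None


def assess_masses(record: PatientRecord, spec: ExpertSystemSpec) -> Optional[float]:
    """R1; ``None`` when no mass is present (inference bypassed)."""
    if not record.mass_present:
        return None
    return _infer_or_raise(
        spec,
        {
            "shape": record.mass_shape,
            "margins": record.mass_margins,
            "density": record.mass_density,
        },
    )


def assess_calcifications(record: PatientRecord, spec: ExpertSystemSpec) -> Optional[float]:
    """R2; ``None`` when no calcifications are present."""
    if not record.calc_present:
        return None
    return _infer_or_raise(
        spec,
        {
            "type": record.calc_type,
            "shape": record.calc_shape,
            "distribution": record.calc_distribution,
        },
    )


def assess_asymmetry_distortion(record: PatientRecord, spec: ExpertSystemSpec) -> Optional[float]:
    """R3; ``None`` only when both asymmetry and distortion are absent."""
    if not record.asymmetry_present and not record.distortion_present:
        return None
    return _infer_or_raise(
        spec,
        {
            "asymmetry": "present" if record.asymmetry_present else "absent",
            "asymmetry_type": record.asymmetry_type,
            "distortion": "present" if record.distortion_present else "absent",
            "distortion_type": record.distortion_type,
        },
    )


def assess_all(record: PatientRecord, specs: Mapping[str, ExpertSystemSpec]) -> SymbolicRiskSet:
    """Run the three expert systems concurrently (they are independent, so
    evaluation order is immaterial) and collect the Symbolic Risks."""
    return SymbolicRiskSet(
        r1=assess_masses(record, specs["masses"]),
        r2=assess_calcifications(record, specs["calcifications"]),
        r3=assess_asymmetry_distortion(record, specs["asymmetry_distortion"]),
    )
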