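"""Generic Mamdani fuzzy-inference engine over categorical antecedents.

The engine implements the classic Mamdani pipeline for expert systems whose
inputs are categorical (singleton membership functions) and whose single
output variable carries ordered triangular consequent sets on the universe
[0, 100]:

1. *firing strength* of a rule = MIN over its antecedent clause memberships
   (with singletons this is 1 iff every clause matches its input category);
2. *implication* (MIN): each fired consequent triangle is clipped at the
   rule's strength;
3. *aggregation* (MAX): pointwise maximum of the clipped sets — several
   rules sharing a consequent label contribute through the MAX of their
   strengths;
4. *defuzzification* (centroid): ∫x·μ(x)dx / ∫μ(x)dx on a uniform
   discretization of [0, 100] (trapezoid quadrature, 10001 points by
   default; configurable per system).

Rule bases live in editable YAML files (see :func:`load_expert_system`),
so a medical team can replace the shipped knowledge bases without touching
code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TriangularMF",
    "FuzzyRule",
    "ExpertSystemSpec",
    "FuzzySpecError",
    "NoRuleFiredError",
    "MAMDANI_CONFIG",
    "default_consequents",
    "firing_strength",
    "aggregate_and_defuzzify",
    "infer",
    "load_expert_system",
    "save_expert_system",
]

#: the fixed inference-engine configuration of the shipped systems
MAMDANI_CONFIG = {
    "structure": "Mamdani",
    "defuzz": "centroid",
    "implication": "MIN",
    "aggregation": "MAX",
}

UNIVERSE = (0.0, 100.0)


class FuzzySpecError(ValueError):
    """An expert-system specification (or an input against it) is invalid."""


class NoRuleFiredError(RuntimeError):
    """No rule fired for the supplied inputs: the aggregate surface is empty."""


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with vertices a <= b <= c on [0, 100].

    Normal (membership 1 at ``b``) and convex.  Shoulder sets at the universe
    edges may be asymmetric (a == b or b == c); interior sets are symmetric
    in the shipped consequent vocabulary.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        lo, hi = UNIVERSE
        if not (lo <= self.a <= self.b <= self.c <= hi):
            raise FuzzySpecError(
                f"triangular vertices must satisfy {lo} <= a <= b <= c <= {hi}, "
                f"got ({self.a}, {self.b}, {self.c})"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mu = np.zeros_like(x)
        if self.b > self.a:
            rising = (x >= self.a) & (x < self.b)
            mu[rising] = (x[rising] - self.a) / (self.b - self.a)
        if self.c > self.b:
            falling = (x > self.b) & (x <= self.c)
            mu[falling] = (self.c - x[falling]) / (self.c - self.b)
        mu[x == self.b] = 1.0
        return mu


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var1 is cat1) AND (var2 is cat2) ... THEN (output is label)."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise FuzzySpecError("rule antecedent must be non-empty")


@dataclass
class ExpertSystemSpec:
    """Declarative Mamdani system: variables, consequents, rules, config."""

    name: str
    variables: dict[str, tuple[str, ...]]
    output_name: str
    consequents: dict[str, TriangularMF]  # insertion order = label order
    rules: list[FuzzyRule]
    config: dict[str, str] = field(default_factory=lambda: dict(MAMDANI_CONFIG))
    resolution: int = 10001

    def __post_init__(self) -> None:
        peaks = [mf.b for mf in self.consequents.values()]
        if any(q <= p for p, q in zip(peaks, peaks[1:])):
            raise FuzzySpecError(
                f"{self.name}: consequent peaks must be strictly increasing, got {peaks}"
            )
        for i, rule in enumerate(self.rules):
            if rule.consequent not in self.consequents:
                raise FuzzySpecError(
                    f"{self.name}: rule {i} references unknown consequent label "
                    f"{rule.consequent!r}"
                )
            for var, cat in rule.antecedent:
                if var not in self.variables:
                    raise FuzzySpecError(
                        f"{self.name}: rule {i} references unknown variable {var!r}"
                    )
                if cat not in self.variables[var]:
                    raise FuzzySpecError(
                        f"{self.name}: rule {i} references unknown category {cat!r} "
                        f"of variable {var!r}"
                    )


def default_consequents(labels: Sequence[str] = ("very-low", "low", "medium", "high", "very-high")) -> dict[str, TriangularMF]:
    """Five ordered risk labels with triangles peaking at 0, 25, 50, 75, 100
    (half-width 25, shoulders clipped at the universe edges)."""
    n = len(labels)
    peaks = np.linspace(UNIVERSE[0], UNIVERSE[1], n)
    half = float(peaks[1] - peaks[0])
    out = {}
    for label, b in zip(labels, (float(p) for p in peaks)):
        out[label] = TriangularMF(max(b - half, UNIVERSE[0]), b, min(b + half, UNIVERSE[1]))
    return out


def firing_strength(
    rule: FuzzyRule,
    inputs: Mapping[str, str],
    variables: Mapping[str, Sequence[str]],
) -> float:
    """MIN over the rule's clause memberships.

    With singleton antecedent sets each clause membership is 1 iff the input
    category equals the clause category, so the strength is 1 iff every
    clause matches, else 0.
    """
    strength = 1.0
    for var, cat in rule.antecedent:
        if var not in variables:
            raise FuzzySpecError(f"unknown variable {var!r} in rule")
        if var not in inputs:
            raise FuzzySpecError(f"inputs missing variable {var!r}")
        value = inputs[var]
        if value not in variables[var]:
            raise FuzzySpecError(
                f"input category {value!r} not declared for variable {var!r}"
            )
        strength = min(strength, 1.0 if value == cat else 0.0)
        if strength == 0.0:
            break
    return strength


def aggregate_and_defuzzify(spec: ExpertSystemSpec, strengths: Mapping[str, float]) -> float:
    """Clip each fired consequent at its strength (MIN implication), take the
    pointwise MAX across labels, and return the centroid of the aggregate.

    Raises :class:`NoRuleFiredError` when every strength is zero.
    """
    if not any(s > 0 for s in strengths.values()):
        raise NoRuleFiredError(f"{spec.name}: no rule fired")
    x = np.linspace(UNIVERSE[0], UNIVERSE[1], spec.resolution)
    mu = np.zeros_like(x)
    for label, s in strengths.items():
        if s <= 0:
            continue
        if label not in spec.consequents:
            raise FuzzySpecError(f"{spec.name}: unknown consequent label {label!r}")
        np.maximum(mu, np.minimum(float(s), spec.consequents[label](x)), out=mu)
    num = np.trapezoid(x * mu, x)
    den = np.trapezoid(mu, x)
    return float(num / den)


def infer(spec: ExpertSystemSpec, inputs: Mapping[str, str]) -> float:
    """Run the full Mamdani pipeline; returns a crisp risk in [0, 100].

    Per-label strength is the MAX over all rules sharing that consequent
    label, making the result invariant under rule reordering.
    """
    strengths = {label: 0.0 for label in spec.consequents}
    for rule in spec.rules:
        s = firing_strength(rule, inputs, spec.variables)
        if s > strengths[rule.consequent]:
            strengths[rule.consequent] = s
    return aggregate_and_defuzzify(spec, strengths)


def _spec_to_doc(spec: ExpertSystemSpec) -> dict[str, Any]:
    return {
        "name": spec.name,
        "variables": {v: list(cats) for v, cats in spec.variables.items()},
        "output": {
            "name": spec.output_name,
            "labels": [
                {"label": lab, "a": mf.a, "b": mf.b, "c": mf.c}
                for lab, mf in spec.consequents.items()
            ],
        },
        "config": dict(spec.config),
        "resolution": spec.resolution,
        "rules": [
            {"if": dict(rule.antecedent), "then": rule.consequent} for rule in spec.rules
        ],
    }


def save_expert_system(spec: ExpertSystemSpec, path: str | Path) -> Path:
    """Write the spec to a YAML rule-base file (inverse of
    :func:`load_expert_system` up to semantic equality)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_spec_to_doc(spec), fh, sort_keys=False)
    return path


def load_expert_system(path: str | Path) -> ExpertSystemSpec:
    """Load and validate a YAML rule-base file.

    The inference configuration is forced to the Mamdani/centroid/MIN/MAX
    setup unless the file explicitly overrides it, in which case a warning
    is emitted (the shipped risk systems all use the fixed configuration).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        variables = {v: tuple(cats) for v, cats in doc["variables"].items()}
        output = doc["output"]
        consequents = {
            entry["label"]: TriangularMF(float(entry["a"]), float(entry["b"]), float(entry["c"]))
            for entry in output["labels"]
        }
        rules = []
        for i, entry in enumerate(doc.get("rules", [])):
            antecedent = tuple((str(v), str(c)) for v, c in entry["if"].items())
            rules.append(FuzzyRule(antecedent=antecedent, consequent=str(entry["then"])))
    except (KeyError, TypeError) as exc:
        raise FuzzySpecError(f"{path}: malformed rule-base file ({exc})") from exc

    config = dict(MAMDANI_CONFIG)
    overrides = {
        k: v for k, v in (doc.get("config") or {}).items() if MAMDANI_CONFIG.get(k) != v
    }
    if overrides:
        warnings.warn(
            f"{path}: overriding fixed inference configuration with {overrides}",
            stacklevel=2,
        )
        config.update(overrides)

    return ExpertSystemSpec(
        name=str(doc.get("name", path.stem)),
        variables=variables,
        output_name=str(output.get("name", "risk")),
        consequents=consequents,
        rules=rules,
        config=config,
        resolution=int(doc.get("resolution", 10001)),
    )
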