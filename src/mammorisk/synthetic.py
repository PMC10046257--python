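"""Synthetic screening-cohort generator and printed reference fixtures.

The generator emulates the schema and class structure of the 130-patient
screening cohort the system was developed on — 21 biopsy-confirmed cancer
cases against 109 controls, mean age 55.2 — without attempting to match the
real data's joint distribution.  The generative mechanism is a latent
liability model:

* each patient draws a liability z ~ N(0, 1); the ``n_cancer`` largest
  liabilities receive the cancer label (optionally degraded by label-noise
  swaps that keep the class counts exact);
* finding-group present/absent flags are Bernoulli with logits shifted by
  ``effect_size * z``, and each categorical descriptor is sampled from its
  vocabulary with softmax probabilities tilted along the documented ordinal
  suspicion scores — so a higher liability drifts every descriptor toward
  its more suspicious categories (monotone coupling, null at effect 0);
* the BI-RADS category blends a liability-quantile draw with a
  label-informed draw according to ``birads_informativeness`` (category 0,
  an incomplete study, is never emitted);
* ages are Normal(mean, sd) truncated to (25, 95).

All randomness flows through one seeded generator, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .datamodel import (
    ASYMMETRY_TYPE,
    BREAST_DENSITY,
    CALC_DISTRIBUTION,
    CALC_SHAPE,
    CALC_TYPE,
    DISTORTION_TYPE,
    FAMILY_HISTORY,
    MASS_DENSITY,
    MASS_MARGINS,
    MASS_SHAPE,
    Cohort,
    PatientRecord,
    validate_record,
)
from .symbolic import SUSPICION_ORDER, SymbolicRiskSet

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "case_study_patient",
    "reference_risk_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults: 130 patients, 21 cancers, mean age 55.2."""

    n: int = 130
    n_cancer: int = 21
    seed: int = 0
    effect_size: float = 2.0
    birads_informativeness: float = 0.8
    label_noise: float = 0.0
    age_mean: float = 55.2
    age_sd: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.n_cancer < self.n:
            raise ValueError(f"need 0 < n_cancer < n, got {self.n_cancer}/{self.n}")
        if not 0 <= self.birads_informativeness <= 1:
            raise ValueError("birads_informativeness must lie in [0, 1]")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


# base presence log-odds at z = 0 (roughly: masses and calcifications common,
# asymmetries and distortions uncommon in a screening population)
_PRESENCE_BASE = {
    "mass": -0.3,
    "calc": -0.5,
    "asymmetry": -1.8,
    "distortion": -2.2,
}

_BIRADS_NO_ZERO = ("1", "2", "3", "4A", "4B", "4C", "5")
# liability-quantile bin edges for the categories above
_BIRADS_QUANTILES = (0.30, 0.55, 0.72, 0.84, 0.92, 0.97, 1.0)
_BIRADS_CANCERISH = (("4A", 0.15), ("4B", 0.35), ("4C", 0.30), ("5", 0.20))
_BIRADS_BENIGNISH = (("1", 0.35), ("2", 0.35), ("3", 0.22), ("4A", 0.08))


def _softmax_pick(
    rng: np.random.Generator,
    vocab: tuple[str, ...],
    scores: dict[str, int],
    tilt: float,
    skip_none: bool = True,
) -> str:
    cats = [c for c in vocab if not (skip_none and c == "none")]
    s = np.array([scores[c] for c in cats], dtype=float)
    s = s / max(s.max(), 1.0)  # normalize ordinals to [0, 1]
    p = np.exp(tilt * s)
    p /= p.sum()
    return cats[rng.choice(len(cats), p=p)]


def _weighted_pick(rng: np.random.Generator, options) -> str:
    cats, weights = zip(*options)
    p = np.asarray(weights, dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> Cohort:
    """Draw a labeled, schema-valid cohort under the latent liability model."""
    rng = np.random.default_rng(config.seed)
    n, c = config.n, config.effect_size
    z = rng.normal(size=n)

    labels = np.array(["non-cancer"] * n, dtype=object)
    top = np.argsort(z, kind="stable")[-config.n_cancer:]
    labels[top] = "cancer"
    if config.label_noise > 0:
        n_flip = rng.binomial(config.n_cancer, config.label_noise)
        if n_flip:
            pos = rng.choice(np.flatnonzero(labels == "cancer"), n_flip, replace=False)
            neg = rng.choice(np.flatnonzero(labels == "non-cancer"), n_flip, replace=False)
            labels[pos], labels[neg] = "non-cancer", "cancer"

    a, b = (25 - config.age_mean) / config.age_sd, (95 - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)

    # liability quantile (within-cohort rank) for the BI-RADS draw
    quantile = (np.argsort(np.argsort(z, kind="stable"), kind="stable") + 0.5) / n

    records = []
    for i in range(n):
        zi = z[i]
        raw: dict = {
            "patient_id": f"syn-{i:04d}",
            "age": round(float(ages[i]), 1),
            "label": labels[i],
        }
        raw["personal_history"] = "yes" if rng.random() < expit(-2.2 + 0.5 * c * zi) else "no"
        raw["family_history"] = _softmax_pick(
            rng, FAMILY_HISTORY[:3], {"none": 0, "minor": 1, "major": 2}, 0.5 * c * zi, skip_none=False
        )

        mass = rng.random() < expit(_PRESENCE_BASE["mass"] + c * zi)
        raw["mass_present"] = mass
        raw["mass_shape"] = _softmax_pick(rng, MASS_SHAPE, SUSPICION_ORDER["mass_shape"], c * zi) if mass else "none"
        raw["mass_margins"] = _softmax_pick(rng, MASS_MARGINS, SUSPICION_ORDER["mass_margins"], c * zi) if mass else "none"
        raw["mass_density"] = _softmax_pick(rng, MASS_DENSITY, SUSPICION_ORDER["mass_density"], c * zi) if mass else "none"

        calc = rng.random() < expit(_PRESENCE_BASE["calc"] + c * zi)
        raw["calc_present"] = calc
        raw["calc_type"] = _softmax_pick(rng, CALC_TYPE, SUSPICION_ORDER["calc_type"], c * zi) if calc else "none"
        raw["calc_shape"] = _softmax_pick(rng, CALC_SHAPE, SUSPICION_ORDER["calc_shape"], c * zi) if calc else "none"
        raw["calc_distribution"] = _softmax_pick(rng, CALC_DISTRIBUTION, SUSPICION_ORDER["calc_distribution"], c * zi) if calc else "none"

        asym = rng.random() < expit(_PRESENCE_BASE["asymmetry"] + c * zi)
        raw["asymmetry_present"] = asym
        raw["asymmetry_type"] = _softmax_pick(rng, ASYMMETRY_TYPE, SUSPICION_ORDER["asymmetry_type"], c * zi) if asym else "none"

        dist = rng.random() < expit(_PRESENCE_BASE["distortion"] + c * zi)
        raw["distortion_present"] = dist
        raw["distortion_type"] = _softmax_pick(rng, DISTORTION_TYPE, SUSPICION_ORDER["distortion_type"], c * zi) if dist else "none"

        raw["breast_density"] = _softmax_pick(
            rng,
            BREAST_DENSITY,
            {"missing": 0, "fatty": 1, "scattered fibroglandular": 2, "heterogeneously dense": 3, "extremely dense": 4},
            0.3 * c * zi,
            skip_none=False,
        )

        if rng.random() < config.birads_informativeness:
            options = _BIRADS_CANCERISH if labels[i] == "cancer" else _BIRADS_BENIGNISH
            raw["birads"] = _weighted_pick(rng, options)
        else:
            raw["birads"] = _BIRADS_NO_ZERO[int(np.searchsorted(_BIRADS_QUANTILES, quantile[i]))]

        records.append(validate_record(raw))

    return Cohort(records=records, provenance=f"generate_cohort({config})")


def case_study_patient() -> PatientRecord:
    """The printed worked-example patient: a 65-year-old with an irregular
    spiculated equal-density mass, associated coarse-heterogeneous grouped
    calcifications, no asymmetry or distortion, heterogeneously dense
    breasts, BI-RADS 4B; biopsy-confirmed cancer."""
    return validate_record(
        {
            "patient_id": "case-study",
            "age": 65,
            "personal_history": "no",
            "family_history": "none",
            "mass_present": "present",
            "mass_shape": "irregular",
            "mass_margins": "spiculated",
            "mass_density": "Homogeneous",  # alias of "equal density"
            "calc_present": "present",
            "calc_type": "associated",
            "calc_shape": "coarse heterogeneous",
            "calc_distribution": "grouped",
            "asymmetry_present": "absent",
            "asymmetry_type": "-",
            "distortion_present": "absent",
            "distortion_type": "-",
            "breast_density": "heterogeneously dense",
            "birads": "4B",
            "label": "cancer",
        }
    )


def reference_risk_fixture() -> tuple[SymbolicRiskSet, float]:
    """The worked example's published component risks: R1 = 89.97,
    R2 = 99.98, R3 null, and Statistical Risk 25.61.

    These decouple aggregation/correction tests (and demonstrations) from
    the unpublished rule bases of the original system.
    """
    return SymbolicRiskSet(r1=89.97, r2=99.98, r3=None), 25.61
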