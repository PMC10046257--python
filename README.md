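# mammorisk

Hybrid symbolic–statistical clinical decision support for breast-cancer
screening risk, computed from radiologist-annotated BI-RADS mammogram
descriptors (no image processing: the inputs are the structured findings a
radiologist already records).

It is aimed at researchers and engineers prototyping decision-support
pipelines over structured mammography reports: it provides the full risk
pipeline as a tested library plus a small CLI, and a synthetic cohort
generator so everything runs without access to clinical data.

## The model

Two inferential arms run concurrently on each screening case:

1. **Symbolic Risks** `R1, R2, R3 ∈ [0, 100]` — three Mamdani fuzzy expert
   systems (singleton categorical antecedents; ordered triangular
   consequents on [0, 100]; MIN implication, MAX aggregation, centroid
   defuzzification) score the three finding groups: masses (shape, margins,
   density), calcifications (type, shape, distribution), and asymmetries &
   architectural distortion. A risk is *null* exactly when its finding
   group is absent on the mammogram.
2. **Statistical Risk** `Rs ∈ [0, 100]` — a bagged decision-tree ensemble
   over every descriptor *except* the expert-assigned BI-RADS category
   (age Min-Max normalized; classes balanced to 200/200 with SMOTE-NC,
   k = 5; stratified 5-fold cross-validated ROC/AUC), scaled to percent.

The arms are aggregated into the **Global Risk**

```
RG = clamp( (ω1·R1 + ω2·R2 + ω3·R3) · log10(Rs), 0, 100 )
```

with base weights ω = (⅓, ⅓, ⅓) and equitable redistribution of the weight
of any null risk. The **Corrected Global Risk** `RG' = min(RG·Fp, 100)`
rescales RG toward the assigned BI-RADS category via the empirical factor
Fp (attenuating for categories 1–2, amplifying with a ceiling cap for
3–4C, saturating to 100 for 5–6; category 0, an incomplete study, is an
error). RG' maps to a warning state: healthy (< 40), dubious (40–60), or
potential cancer case (≥ 60), each with a recommendation.

The shipped fuzzy rule bases are generated from documented ordinal
suspicion orderings of the BI-RADS lexicon — they are total and monotone,
and live in editable YAML files (`src/mammorisk/rulebases/`) so a medical
team can substitute its own knowledge base.

## Worked example

The bundled case-study patient (age 65; irregular spiculated equal-density
mass; associated coarse-heterogeneous grouped calcifications; no asymmetry
or distortion; BI-RADS 4B), assessed with externally supplied component
risks R1 = 89.97, R2 = 99.98, R3 null and Rs = 25.61:

```bash
mammorisk assess --patient patient.json \
    --r1 89.97 --r2 99.98 --r3 null --rs 25.61
```

prints

```json
{
 "patient_id": "case-study",
 "R1": 89.97, "R2": 99.98, "R3": null,
 "weights": [0.5, 0.5, 0.0],
 "Rs": 25.61,
 "RG": 100.0,
 "Fp": 1.0,
 "RG_corrected": 100.0,
 "state": "potential",
 "recommendation": "Perform confirmatory tests.",
 "notes": ["maximum alert: Corrected Global Risk at its ceiling"]
}
```

Reading: the null third risk redistributes the weights to (0.5, 0.5, 0);
the weighted symbolic sum (94.975) times log10(25.61) ≈ 1.408 exceeds the
ceiling, so RG caps at 100; at BI-RADS 4B the amplify-branch factor is
capped at Fc = 100/RG = 1, leaving RG' = 100 — a maximum-alert potential
case referred for confirmatory tests.

A full synthetic workflow:

```bash
mammorisk generate-cohort --seed 1 --out cohort.csv     # 130 patients, 21 cancers
mammorisk train --cohort cohort.csv --out model.joblib --seed 1
mammorisk evaluate --cohort cohort.csv --model model.joblib
```

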