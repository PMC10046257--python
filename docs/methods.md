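# Methods

## Scope and data model

The package scores breast-cancer risk from structured screening data: the
general patient fields (age, personal cancer history, family history) and
the BI-RADS-lexicon mammogram descriptors (mass shape/margins/density,
calcification type/shape/distribution, asymmetry type, architectural
distortion type, breast tissue density, and the assigned BI-RADS category
0–6 with 4A/4B/4C). All categorical values are validated against controlled
vocabularies and canonicalized case-insensitively with a small alias table
for spellings that vary across the literature ("popcorn" ↔ coarse
calcifications; "homogeneous" ↔ equal-density mass — the latter is needed
because both spellings are in clinical use for the same finding). Finding
sub-fields of an absent group are forced to "none"; a concrete non-none
value on an absent group is rejected as inconsistent rather than silently
dropped. The outcome label (`cancer`/`non-cancer`) is optional: screening
mode carries none, training and evaluation require it.

## Mamdani engine

Antecedents are singleton membership functions (the inputs are categories,
each pointing at a single value), so a rule's firing strength — MIN over
clause memberships — is 1 iff every clause matches, else 0. Consequents are
normal, convex triangular sets on [0, 100]; the shipped vocabulary has five
ordered labels peaking at 0, 25, 50, 75, 100 with half-width 25 (the two
shoulders clipped at the universe edges). Implication is MIN (clipping),
aggregation is MAX, and defuzzification is the centroid of the aggregate
surface.

Numerical choice: the centroid is evaluated by trapezoid quadrature on a
uniform grid of 10 001 points. The integrand is piecewise linear between
membership-function kinks, and at this resolution the centroid error on
randomized systems is ≈ 4·10⁻⁵ risk units (verified in the test suite
against an independent ≥ 10⁵-point brute-force integration), comfortably
inside the 10⁻³ agreement the package promises. The resolution is stored
per rule-base file and can be changed there.

Per-label strength when several rules share a consequent is the MAX of
their firing strengths (standard Mamdani, and what makes inference
invariant under rule reordering). An input combination matched by no rule
raises an explicit error naming the combination; the shipped rule bases
never trigger it (they are total by construction).

## Shipped rule bases

The three expert systems (masses: shape × margins × density, 120 rules;
calcifications: type × shape × distribution, 270 rules; asymmetry &
distortion: presence and type of each sub-group, 48 rules) are generated
from ordinal suspicion scores assigned to every category of every
antecedent, e.g. mass shape none(0) < oval(1) ≈ round(1) < lobulated(2) <
irregular(3); margins circumscribed(1) < obscured(2) < micro-lobulated(3)
< indistinct(4) < spiculated(5); calcification shapes typically-benign(1)
< amorphous/coarse-heterogeneous(3) < fine-pleomorphic/fine-linear(4) <
fine-linear-branching(5). Mass density is treated as a minor modifier
(low ≈ equal < high). Each combination's summed score is mapped
proportionally onto the five consequent labels. Because exactly one rule
fires per combination and the label index is non-decreasing in every
antecedent's score, the systems are provably ordinal-monotone; the test
suite still verifies this exhaustively over all 438 combinations.

These knowledge bases are a reasonable clinical ordering, not a validated
one: the design intent is that a medical team edits the YAML files. No
claim is made that they reproduce any particular published risk values
produced by proprietary rule bases.

## Statistical arm

Features are the full descriptor set *excluding the BI-RADS category*
(deliberately, so the statistical prediction stays independent of the index
used later for correction), with age Min-Max normalized by training-data
bounds (scoring-time ages outside the bounds clip to [0, 1] with a
warning) and categoricals integer-coded.

SMOTE-NC is implemented in-package: both classes are grown to a common
target of 200 rows using k = 5 same-class nearest neighbours, numeric
features interpolated uniformly between seed point and neighbour,
categorical features set by majority vote among the k neighbours (ties
break to the lowest code), and a per-mismatch distance penalty equal to the
median of the class's numeric-feature standard deviations. Original rows
are preserved verbatim and first.

The classifier is a bagging ensemble of 100 unlimited-depth Gini decision
trees (the ensemble size and tree settings are common bagged-trees
defaults; both configurable). Performance is estimated with stratified
5-fold cross-validation in which augmentation runs *inside each training
fold only* — held-out rows are always original patients. The alternative
(augment first, then split) leaks synthetic copies of held-out patients
into training and inflates AUC; the leakage-free ordering is the default
and the package makes no attempt to match optimistic figures obtainable the
other way. AUC is the rank (Mann–Whitney) statistic with half-credit for
ties; ROC points for export come from scikit-learn.

## Aggregation and correction

`RG = clamp((ω1·R1 + ω2·R2 + ω3·R3)·log10(Rs), 0, 100)`. The log term
multiplies the entire weighted sum. Rs is floored at 1 before the
logarithm so the term is never negative — the statistical arm can amplify
risk, never drive it below zero. Null risks contribute zero and their base
weight (default ⅓ each) is redistributed equally among surviving risks. A
findings-free mammogram is reported as RG = 0 / healthy with an explicit
"no findings" note instead of running inference on nothing.

The correction factor uses f(RG) = 10/(RG+10) and Fc = 100/RG with numeric
BI-RADS levels at the categories' ordinal positions (1, 2, 3, 4A, 4B, 4C →
1…6, configurable — the worked-example arithmetic is insensitive to this
convention):

* categories 1–2: Fp = 1/(k + f(RG)), k = −level + 3.5 (always < 1:
  attenuates);
* categories 3–4C: Fp = min(t + f(RG), Fc), t = level − 1.5 (amplifies,
  but the Fc cap keeps RG′ ≤ 100);
* categories 5–6: Fp = Fc (saturates RG′ to 100 for any RG > 0).

BI-RADS 0 is an incomplete study: the correction is undefined and the
pipeline raises an error rather than guessing. RG = 0 skips the correction
(Fp = 1) with a warning, since both Fc and the saturate branch are
undefined there. States on RG′ are half-open: healthy < 40 ≤ dubious
< 60 ≤ potential; thresholds configurable.

## Synthetic cohorts

The generator emulates the schema and class structure of the development
cohort — 130 patients, 21 cancers vs 109 controls, mean age 55.2 (sd 10,
truncated to 25–95) — via a latent liability model: z ~ N(0, 1) per
patient; the top-21 liabilities get the cancer label (optional label-noise
swaps keep counts exact); finding presence flags are Bernoulli with logits
shifted by `effect_size · z` around screening-plausible base rates (masses
≈ 0.43, calcifications ≈ 0.38, asymmetries ≈ 0.14, distortions ≈ 0.10 at
z = 0); each categorical descriptor is drawn with softmax probabilities
tilted along its suspicion ordinals by `effect_size · z`; BI-RADS blends a
liability-quantile draw with a label-informed draw per
`birads_informativeness` (default 0.8; category 0 never emitted). The
default `effect_size` of 2.0 is chosen to represent a strongly informative
descriptor set, the regime in which the original system was demonstrated.

What the generator does *not* emulate: the real cohort's joint descriptor
distribution, reader variability, correlated findings within a breast, or
site effects. Passing tests therefore demonstrate that the machinery
(validation, inference, augmentation, training, aggregation) behaves
correctly and recovers planted signal — not that the shipped rule bases or
a classifier trained on synthetic data would perform clinically.

## Problem sizes and determinism

The test suite and acceptance script run the pipeline at the study's own
scale (130-patient cohorts, 200/class augmentation, 100-tree ensembles,
5 seeds for stochastic properties), which keeps the whole suite under a
minute on one CPU. Every stochastic step takes an explicit seed or NumPy
Generator and is bit-reproducible under it.

## Known limitations

* The shipped rule bases encode a generic ordinal reading of the BI-RADS
  lexicon, not validated clinical knowledge.
* The empirical correction-factor table is taken as given; no recalibration
  against outcome data is attempted (by design — it exists to mirror
  BI-RADS-driven practice, not to improve discrimination).
* Cohort-level performance numbers depend entirely on the synthetic
  generator's assumptions; they are properties of the machinery, not
  clinical estimates.
* The sub-category level numbers for 4A/4B/4C in the correction are an
  ordinal convention; other conventions are accepted via configuration.
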