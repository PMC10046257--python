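"""Mamdani engine: firing strengths, centroid defuzzification, file I/O.

The engine is checked against an independent fine-grid oracle: a separate
brute-force implementation of clip-MAX-centroid over >= 10^5 trapezoid
points, written here from the definitions and never sharing code with the
engine under test.
"""

import numpy as np
import pytest
import yaml

from mammorisk.fuzzy import (
    ExpertSystemSpec,
    FuzzyRule,
    FuzzySpecError,
    NoRuleFiredError,
    TriangularMF,
    aggregate_and_defuzzify,
    default_consequents,
    firing_strength,
    infer,
    load_expert_system,
    save_expert_system,
)

VARS = {"shape": ("oval", "irregular"), "margins": ("circumscribed", "spiculated")}


def rule(consequent="high", **clauses):
    clauses = clauses or {"shape": "oval"}
    return FuzzyRule(antecedent=tuple(clauses.items()), consequent=consequent)


def make_spec(rules, consequents=None):
    return ExpertSystemSpec(
        name="toy",
        variables=VARS,
        output_name="risk",
        consequents=consequents or default_consequents(),
        rules=rules,
    )


# ---------------------------------------------------------------- oracle ---
def oracle_centroid(triangles, strengths, n_points=200_001):
    """Brute-force Mamdani aggregate centroid on a fine uniform grid."""
    x = np.linspace(0.0, 100.0, n_points)
    mu = np.zeros_like(x)
    for (a, b, c), s in zip(triangles, strengths):
        left = (x - a) / (b - a) if b > a else np.ones_like(x)
        right = (c - x) / (c - b) if c > b else np.ones_like(x)
        tri = np.clip(np.minimum(left, right), 0.0, 1.0)
        tri[(x < a) | (x > c)] = 0.0
        mu = np.maximum(mu, np.minimum(tri, s))
    return np.trapezoid(x * mu, x) / np.trapezoid(mu, x)


class TestFiringStrength:
    def test_all_singletons_match(self):
        r = rule(shape="irregular", margins="spiculated")
        assert firing_strength(r, {"shape": "irregular", "margins": "spiculated"}, VARS) == 1

    def test_one_clause_fails(self):
        r = rule(shape="irregular", margins="spiculated")
        assert firing_strength(r, {"shape": "oval", "margins": "spiculated"}, VARS) == 0

    def test_missing_variable_is_spec_error(self):
        with pytest.raises(FuzzySpecError, match="missing"):
            firing_strength(rule(shape="oval", margins="spiculated"), {"shape": "oval"}, VARS)

    def test_unknown_category_is_spec_error(self):
        with pytest.raises(FuzzySpecError):
            firing_strength(rule(shape="oval"), {"shape": "weird"}, VARS)


class TestDefuzzify:
    @pytest.mark.parametrize(
        "strengths, expected",
        [
            ({"medium": 1.0}, 50.0),  # symmetric triangle at full strength
            ({"high": 1.0}, 75.0),
            ({"low": 1.0, "high": 1.0}, 50.0),  # mirror-symmetric aggregate
        ],
    )
    def test_symmetric_cases(self, strengths, expected):
        spec = make_spec([rule()])
        assert aggregate_and_defuzzify(spec, strengths) == pytest.approx(expected, abs=1e-9)

    def test_clipped_triangle_matches_oracle(self):
        spec = make_spec([rule()])
        got = aggregate_and_defuzzify(spec, {"high": 0.5})
        expected = oracle_centroid([(50, 75, 100)], [0.5])
        assert got == pytest.approx(expected, abs=1e-3)

    def test_all_strengths_zero_raises(self):
        spec = make_spec([rule()])
        with pytest.raises(NoRuleFiredError):
            aggregate_and_defuzzify(spec, {"high": 0.0})

    def test_shoulder_peak_not_centroid(self):
        # edge shoulders are asymmetric: centroid pulled inside the universe
        spec = make_spec([rule()])
        assert aggregate_and_defuzzify(spec, {"very-high": 1.0}) == pytest.approx(275 / 3, abs=1e-3)


class TestInfer:
    def test_always_matching_rule_hits_label_centroid(self):
        spec = make_spec(
            [rule("very-high", shape=s, margins=m) for s in VARS["shape"] for m in VARS["margins"]]
        )
        out = infer(spec, {"shape": "oval", "margins": "circumscribed"})
        assert out == pytest.approx(275 / 3, abs=1e-3)

    def test_invariant_under_rule_reordering(self):
        rules = [
            rule("low", shape="oval", margins="circumscribed"),
            rule("high", shape="oval", margins="spiculated"),
            rule("medium", shape="oval"),
        ]
        spec = make_spec(rules)
        spec_rev = make_spec(rules[::-1])
        inputs = {"shape": "oval", "margins": "spiculated"}
        assert infer(spec, inputs) == infer(spec_rev, inputs)

    def test_randomized_systems_match_fine_grid_oracle(self):
        """Engine output equals the independent brute-force Mamdani within 1e-3."""
        rng = np.random.default_rng(42)
        labels = ("l0", "l1", "l2", "l3")
        for _ in range(25):
            peaks = np.sort(rng.uniform(1, 99, size=len(labels)))
            while np.any(np.diff(peaks) < 1e-3):
                peaks = np.sort(rng.uniform(1, 99, size=len(labels)))
            tris = []
            for b in peaks:
                a = rng.uniform(0, b)
                c = rng.uniform(b, 100)
                tris.append((a, b, c))
            consequents = {lab: TriangularMF(*t) for lab, t in zip(labels, tris)}
            strengths = {lab: float(rng.random() < 0.7) * rng.uniform(0.05, 1) for lab in labels}
            if not any(strengths.values()):
                strengths["l0"] = 0.5
            spec = ExpertSystemSpec(
                name="rand", variables=VARS, output_name="risk",
                consequents=consequents, rules=[rule("l0")],
            )
            got = aggregate_and_defuzzify(spec, strengths)
            want = oracle_centroid(tris, [strengths[lab] for lab in labels])
            assert got == pytest.approx(want, abs=1e-3)
            assert 0 <= got <= 100

    def test_output_bounded_random_rule_bases(self):
        rng = np.random.default_rng(0)
        labels = tuple(default_consequents())
        for _ in range(100):
            rules = [
                rule(labels[rng.integers(len(labels))],
                     shape=VARS["shape"][rng.integers(2)],
                     margins=VARS["margins"][rng.integers(2)])
                for _ in range(rng.integers(1, 6))
            ]
            spec = make_spec(rules)
            inputs = {"shape": VARS["shape"][rng.integers(2)], "margins": VARS["margins"][rng.integers(2)]}
            try:
                assert 0 <= infer(spec, inputs) <= 100
            except NoRuleFiredError:
                pass


class TestSpecValidationAndIO:
    def test_non_increasing_consequent_peaks_rejected(self):
        bad = {"low": TriangularMF(0, 50, 100), "high": TriangularMF(0, 50, 100)}
        with pytest.raises(FuzzySpecError, match="strictly increasing"):
            make_spec([rule("low")], consequents=bad)

    def test_rule_with_unknown_label_rejected_with_index(self):
        with pytest.raises(FuzzySpecError, match="rule 0.*ultra-high"):
            make_spec([rule("ultra-high", shape="oval")])

    def test_round_trip_semantic_equality(self, tmp_path):
        spec = make_spec([rule("medium", shape="oval"), rule("very-high", shape="irregular")])
        path = save_expert_system(spec, tmp_path / "toy.yaml")
        back = load_expert_system(path)
        assert back.variables == spec.variables
        assert back.consequents == spec.consequents
        assert back.rules == spec.rules
        assert back.config == spec.config

    def test_load_error_for_undeclared_label(self, tmp_path):
        spec = make_spec([rule("medium", shape="oval")])
        path = save_expert_system(spec, tmp_path / "toy.yaml")
        doc = yaml.safe_load(path.read_text())
        doc["rules"][0]["then"] = "ultra-high"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(FuzzySpecError, match="ultra-high"):
            load_expert_system(path)

    def test_config_override_warns(self, tmp_path):
        spec = make_spec([rule("medium", shape="oval")])
        path = save_expert_system(spec, tmp_path / "toy.yaml")
        doc = yaml.safe_load(path.read_text())
        doc["config"]["defuzz"] = "bisector"
        path.write_text(yaml.safe_dump(doc))
        with pytest.warns(UserWarning, match="overriding"):
            loaded = load_expert_system(path)
        assert loaded.config["defuzz"] == "bisector"
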