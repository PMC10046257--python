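"""Classifier metrics against brute-force oracles, and cohort evaluation."""

import dataclasses
import itertools
import warnings

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from mammorisk.datamodel import Cohort
from mammorisk.evaluation import (
    EvaluationError,
    auc,
    binarize,
    confusion_metrics,
    evaluate_cohort,
    mcc,
)
from mammorisk.synthetic import GeneratorConfig, generate_cohort


def brute_confusion(predicted, truth):
    """Oracle: explicit loop counting of the four confusion cells."""
    cells = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for p, t in zip(predicted, truth):
        if t == "cancer":
            cells["TP" if p == "cancer" else "FN"] += 1
        else:
            cells["FP" if p == "cancer" else "TN"] += 1
    return cells


def brute_auc(scores, truth):
    """Oracle: exhaustive case-control pair counting with half credit for ties."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBinarize:
    def test_threshold_is_inclusive(self):
        assert binarize([59.9, 60.0, 100.0], 60.0) == ["non-cancer", "cancer", "cancer"]

    def test_threshold_zero_flags_everyone(self):
        assert binarize([0.0, 50.0], 0.0) == ["cancer", "cancer"]

    def test_threshold_sweep_matches_rank_auc(self):
        """The ROC staircase traced by sweeping the threshold integrates to
        the rank-based AUC."""
        rng = np.random.default_rng(3)
        scores = np.round(rng.uniform(0, 100, 25), 1)
        truth01 = rng.integers(0, 2, 25)
        while truth01.sum() in (0, len(truth01)):
            truth01 = rng.integers(0, 2, 25)
        truth = ["cancer" if t else "non-cancer" for t in truth01]
        points = []
        for thr in sorted(set(scores)) + [101.0]:
            cells = brute_confusion(binarize(scores, thr), truth)
            tpr = cells["TP"] / (cells["TP"] + cells["FN"])
            fpr = cells["FP"] / (cells["FP"] + cells["TN"])
            points.append((fpr, tpr))
        points = sorted(points) + [(1.0, 1.0)]
        area = np.trapezoid([p[1] for p in points], [p[0] for p in points])
        assert area == pytest.approx(auc(scores, truth01), abs=1e-9)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        truth = ["cancer"] * 3 + ["non-cancer"] * 5
        m = confusion_metrics(truth, truth)
        assert (m["sensitivity_pct"], m["specificity_pct"]) == (100.0, 100.0)
        assert (m["false_negative_rate_pct"], m["false_positive_rate_pct"]) == (0.0, 0.0)

    def test_all_positive_on_study_imbalance(self):
        truth = ["cancer"] * 21 + ["non-cancer"] * 109
        m = confusion_metrics(["cancer"] * 130, truth)
        assert m["sensitivity_pct"] == 100.0
        assert m["specificity_pct"] == 0.0

    def test_mirrors_printed_operating_point(self):
        """TP=19, FN=2, TN=97, FP=11 gives sensitivity 90.48 / specificity 89.81."""
        truth = ["cancer"] * 21 + ["non-cancer"] * 108
        predicted = (["cancer"] * 19 + ["non-cancer"] * 2
                     + ["cancer"] * 11 + ["non-cancer"] * 97)
        m = confusion_metrics(predicted, truth)
        assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (19, 2, 11, 97)
        assert m["sensitivity_pct"] == pytest.approx(90.48, abs=0.005)
        assert m["specificity_pct"] == pytest.approx(89.81, abs=0.005)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(4, 31)
            truth = ["cancer" if t else "non-cancer" for t in rng.integers(0, 2, n)]
            if len(set(truth)) < 2:
                continue
            predicted = ["cancer" if t else "non-cancer" for t in rng.integers(0, 2, n)]
            m = confusion_metrics(predicted, truth)
            cells = brute_confusion(predicted, truth)
            assert {k: m[k] for k in cells} == cells
            assert m["sensitivity_pct"] + m["false_negative_rate_pct"] == pytest.approx(100.0)
            assert m["specificity_pct"] + m["false_positive_rate_pct"] == pytest.approx(100.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(EvaluationError, match="both classes"):
            confusion_metrics(["cancer"], ["cancer"])


class TestMcc:
    def test_perfect_and_inverted(self):
        assert mcc(10, 0, 15, 0) == 1.0
        assert mcc(0, 15, 0, 10) == -1.0

    def test_printed_operating_point_against_formula(self):
        tp, fn, tn, fp = 19, 2, 97, 11
        expected = (tp * tn - fp * fn) / np.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc(tp, fp, tn, fn) == pytest.approx(expected)

    def test_degenerate_denominator_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="denominator"):
            assert mcc(0, 0, 5, 3) == 0.0

    def test_random_instances_match_sklearn(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(6, 31))
            truth = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            if len(set(truth)) < 2 or len(set(pred)) < 2:
                continue
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            tn = int(np.sum((pred == 0) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            assert mcc(tp, fp, tn, fn) == pytest.approx(matthews_corrcoef(truth, pred))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([90, 80, 10, 20], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([50, 50, 50, 50], [1, 0, 1, 0]) == 0.5

    def test_toy_vector_matches_pair_counting(self):
        scores = [10, 40, 40, 70, 20, 90]
        truth = [0, 1, 0, 1, 0, 1]
        assert auc(scores, truth) == pytest.approx(brute_auc(scores, truth))

    def test_random_instances_match_brute_force_and_sklearn(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 100, n), 0)  # rounding forces ties
            got = auc(scores, truth)
            assert got == pytest.approx(brute_auc(scores, truth))
            assert got == pytest.approx(roc_auc_score(truth, scores))

    def test_invariant_to_ordering(self):
        rng = np.random.default_rng(19)
        scores = rng.uniform(0, 100, 20)
        truth = rng.integers(0, 2, 20)
        truth[0], truth[1] = 1, 0
        perm = rng.permutation(20)
        assert auc(scores, truth) == pytest.approx(auc(scores[perm], truth[perm]))


class TestEvaluateCohort:
    def test_full_pipeline_on_held_out_cohort(self, specs, strong_model):
        test_cohort = generate_cohort(GeneratorConfig(seed=107))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g, c = evaluate_cohort(test_cohort, specs, strong_model)
        assert g.tp + g.fp + g.tn + g.fn == 130
        assert g.variant == "global" and c.variant == "corrected_global"
        assert 0 <= g.auc <= 1 and 0 <= c.auc <= 1

    def test_corrected_sensitivity_at_least_global(self, specs, strong_model):
        """With a label-informed BI-RADS generator the correction pushes
        suspicious cases up, so corrected sensitivity >= global sensitivity."""
        test_cohort = generate_cohort(GeneratorConfig(seed=211))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g, c = evaluate_cohort(test_cohort, specs, strong_model)
        assert c.sensitivity >= g.sensitivity

    def test_deterministic_under_fixed_seed(self, specs, strong_model):
        cohort = generate_cohort(GeneratorConfig(seed=311))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = evaluate_cohort(cohort, specs, strong_model)
            second = evaluate_cohort(cohort, specs, strong_model)
        assert first == second

    def test_unlabeled_record_rejected(self, specs, strong_model, strong_cohort):
        records = [dataclasses.replace(strong_cohort.records[0], label=None)]
        cohort = Cohort(records=records)
        with pytest.raises(EvaluationError, match="unlabeled"):
            evaluate_cohort(cohort, specs, strong_model)
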