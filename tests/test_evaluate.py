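import math

import numpy as np
import pytest

from mmis import (
    ConfusionMatrix,
    StratificationPolicy,
    confusion_at_threshold,
    full_report,
    metrics_from_confusion,
    optimal_threshold,
    pr_average_precision,
    roc_auc,
    score_distribution_export,
    stratified_report,
)
from mmis.evaluate import EvaluationError


def _oracle_metrics(tp, tn, fp, fn):
    """Independently coded formulas (fractions, not percentages)."""
    out = {}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["npv"] = tn / (tn + fn) if tn + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["fpr"] = fp / (tn + fp) if tn + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["fnr"] = fn / (tp + fn) if tp + fn else None
    out["accuracy"] = (tp + tn) / (tp + tn + fp + fn)
    p, r = out["precision"], out["recall"]
    out["f1"] = 2 * p * r / (p + r) if p is not None and r is not None and p + r else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(den) if den else None
    return out


def _pair_auc(scores, labels):
    """Mann-Whitney oracle: (concordant + half-ties) / (n1 * n0)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestConfusionAtThreshold:
    def test_simple_split(self):
        cm = confusion_at_threshold([0.9, 0.4], [1, 0], 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_score_equal_to_threshold_is_negative(self):
        cm = confusion_at_threshold([0.5], [1], 0.5)
        assert (cm.tp, cm.fn) == (0, 1)

    def test_matches_brute_force_count(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        t = 0.4
        cm = confusion_at_threshold(scores, labels, t)
        tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 1)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)

    def test_empty_and_bad_labels_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_at_threshold([], [], 0.5)
        with pytest.raises(EvaluationError):
            confusion_at_threshold([0.5], [2], 0.5)


class TestMetricsFromConfusion:
    def test_published_worked_example(self):
        """The (269, 488, 189, 12) matrix reproduces its reported panel."""
        rep = metrics_from_confusion(ConfusionMatrix(269, 488, 189, 12)).rounded()
        assert rep["precision"] == 58.73
        assert rep["npv"] == 97.60
        assert rep["specificity"] == 72.08
        assert rep["fpr"] == 27.92
        assert rep["recall"] == 95.73
        assert rep["fnr"] == 4.27
        assert rep["accuracy"] == 79.02
        assert rep["mcc"] == 0.618
        assert rep["f1"] == 0.728

    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionMatrix(10, 10, 0, 0))
        assert rep.recall == 100.0 and rep.specificity == 100.0
        assert rep.fpr == 0.0 and rep.fnr == 0.0
        assert rep.mcc == 1.0 and rep.f1 == 1.0

    def test_matches_independent_formulas(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + tn + fp + fn == 0:
                continue
            rep = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn))
            oracle = _oracle_metrics(tp, tn, fp, fn)
            for name in ("precision", "npv", "specificity", "fpr", "recall",
                         "fnr", "accuracy"):
                got = getattr(rep, name)
                want = oracle[name]
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(100 * want, abs=1e-12)
            for name in ("mcc", "f1"):
                got, want = getattr(rep, name), oracle[name]
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_undefined_ratio_reported_as_marker_not_zero(self):
        rep = metrics_from_confusion(ConfusionMatrix(0, 5, 0, 0))
        assert rep.precision is None and rep.recall is None

    def test_complementarity_identities(self, rng):
        """fpr + specificity = 100 and fnr + recall = 100 whenever defined."""
        for _ in range(20):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 30, 4))
            rep = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn))
            assert rep.fpr + rep.specificity == pytest.approx(100.0)
            assert rep.fnr + rep.recall == pytest.approx(100.0)


class TestRocAuc:
    def test_perfect_scores(self):
        _, auc = roc_auc([0, 1, 0, 1], [0, 1, 0, 1])
        assert auc == 1.0

    def test_all_identical_scores_give_half(self):
        _, auc = roc_auc([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_curve_endpoints_and_threshold_monotonicity(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        curve, _ = roc_auc(scores, labels)
        assert (curve.x[0], curve.y[0]) == (0.0, 0.0)
        assert (curve.x[-1], curve.y[-1]) == (1.0, 1.0)
        assert (np.diff(curve.thresholds) < 0).all()

    def test_equals_pairwise_mann_whitney(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_pair_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.2, 0.8], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        _, ap = pr_average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == 1.0

    def test_identical_scores_give_prevalence(self):
        _, ap = pr_average_precision([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert ap == pytest.approx(0.3)

    def test_matches_brute_force_sweep(self, rng):
        scores = np.round(rng.random(20), 1)
        labels = rng.integers(0, 2, 20)
        labels[0] = 1
        _, ap = pr_average_precision(scores, labels)
        # oracle: explicit sweep over distinct thresholds descending
        uniq = sorted(set(scores), reverse=True)
        n1 = labels.sum()
        prev_r, total = 0.0, 0.0
        for t in uniq:
            sel = scores >= t
            tp = int((labels[sel] == 1).sum())
            p = tp / sel.sum()
            r = tp / n1
            total += (r - prev_r) * p
            prev_r = r
        assert ap == pytest.approx(total, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import average_precision_score

        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1
        _, ap = pr_average_precision(scores, labels)
        assert ap == pytest.approx(average_precision_score(labels, scores), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(EvaluationError):
            pr_average_precision([0.1, 0.2], [0, 0])


class TestOptimalThreshold:
    def test_separable_scores_pick_boundary(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1]
        curve, _ = roc_auc(scores, labels)
        t = optimal_threshold(curve)
        # smallest score-derived threshold achieving J=1 under score > t
        assert t == pytest.approx(0.3)

    def test_identical_scores_return_smallest_threshold(self):
        curve, _ = roc_auc([0.4] * 4, [0, 1, 0, 1])
        assert optimal_threshold(curve) == pytest.approx(curve.thresholds[-1])

    def test_matches_exhaustive_search(self, rng):
        scores = np.round(rng.random(10), 1)
        labels = rng.integers(0, 2, 10)
        labels[:2] = [0, 1]
        curve, _ = roc_auc(scores, labels)
        t = optimal_threshold(curve)

        def j_at(thr):
            pred = scores > thr
            tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
            return tpr - fpr

        best_j = max(j_at(thr) for thr in curve.thresholds)
        assert j_at(t) == pytest.approx(best_j, abs=1e-12)
        # no smaller candidate achieves the same J
        for thr in curve.thresholds:
            if thr < t:
                assert j_at(thr) < best_j - 1e-12


class TestFullReport:
    def test_missing_scores_counted_and_excluded(self):
        scores = [0.9, 0.8, np.nan, 0.2, 0.1, np.nan, 0.7, 0.3, 0.6, 0.4]
        labels = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
        rep = full_report(scores, labels, 0.5)
        assert rep.missing == 2
        cm = confusion_at_threshold(scores, labels, 0.5)
        assert cm.total == 8

    def test_no_missing(self):
        rep = full_report([0.9, 0.1], [1, 0], 0.5)
        assert rep.missing == 0

    def test_fields_equal_component_operations(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        rep = full_report(scores, labels, 0.5)
        parts = metrics_from_confusion(confusion_at_threshold(scores, labels, 0.5))
        assert rep.accuracy == parts.accuracy and rep.mcc == parts.mcc
        _, auc = roc_auc(scores, labels)
        _, ap = pr_average_precision(scores, labels)
        assert rep.auc == auc and rep.average_precision == ap

    def test_permutation_invariance(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        perm = rng.permutation(30)
        r1 = full_report(scores, labels, 0.5)
        r2 = full_report(scores[perm], labels[perm], 0.5)
        assert r1.rounded() == r2.rounded()


class TestStratifiedReport:
    def test_hand_counted_example(self):
        rep = stratified_report([0.9, 0.05, 0.5], [1, 0, 1])
        assert rep.proportion_classified == pytest.approx(200 / 3)
        assert rep.accuracy_of_recommended == pytest.approx(100.0)
        assert rep.overall_accuracy == pytest.approx(200 / 3)
        assert rep.proportion_indeterminate == pytest.approx(100 / 3)

    def test_everything_in_vus_band(self):
        rep = stratified_report([0.3, 0.5, 0.6], [1, 0, 1])
        assert rep.proportion_classified == 0.0
        assert rep.accuracy_of_recommended is None

    def test_degenerate_policy_reduces_to_binary(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        policy = StratificationPolicy(0.5, 0.5 - 1e-12)
        rep = stratified_report(scores, labels, policy)
        cm = confusion_at_threshold(scores, labels, 0.5)
        binary_acc = 100.0 * (cm.tp + cm.tn) / cm.total
        assert rep.proportion_classified == pytest.approx(100.0)
        assert rep.accuracy_of_recommended == pytest.approx(binary_acc)

    def test_invalid_policy_rejected(self):
        with pytest.raises(EvaluationError):
            StratificationPolicy(0.15, 0.75)


class TestScoreDistribution:
    def test_benign_misclassification_hand_count(self):
        _, rates = score_distribution_export(
            [0.1, 0.6, 0.9], [0, 0, 1], threshold=0.5
        )
        assert rates["benign_misclassification"] == pytest.approx(50.0)
        assert rates["pathogenic_misclassification"] == pytest.approx(0.0)

    def test_all_correct_gives_zero_rates(self):
        _, rates = score_distribution_export([0.1, 0.9], [0, 1], 0.5)
        assert rates["benign_misclassification"] == 0.0
        assert rates["pathogenic_misclassification"] == 0.0

    def test_rates_consistent_with_confusion_matrix(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        _, rates = score_distribution_export(scores, labels, 0.5)
        cm = confusion_at_threshold(scores, labels, 0.5)
        assert rates["benign_misclassification"] == pytest.approx(
            100.0 * cm.fp / (cm.fp + cm.tn)
        )
        assert rates["pathogenic_misclassification"] == pytest.approx(
            100.0 * cm.fn / (cm.tp + cm.fn)
        )
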