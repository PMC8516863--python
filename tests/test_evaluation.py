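import numpy as np
import pandas as pd
import pytest

from ecgtfmap.evaluation import (aggregate, build_report, confusion_matrix,
                                 per_class_metrics, roc_pr_curves)
from ecgtfmap.io import CLASSES


class TestConfusionMatrix:
    def test_perfect_one_per_class(self):
        cm = confusion_matrix(CLASSES, CLASSES)
        np.testing.assert_array_equal(cm, np.eye(9, dtype=int))

    def test_all_predicted_first_class(self):
        cm = confusion_matrix(CLASSES, ["NSR"] * 9)
        assert cm[:, 0].sum() == 9 and cm.sum() == 9

    def test_hand_tally(self):
        true = ["AF", "AF", "NSR", "NSR", "NSR", "PVC", "PVC", "PVC",
                "AF", "NSR", "PVC", "AF"]
        pred = ["AF", "NSR", "NSR", "NSR", "AF", "PVC", "PVC", "NSR",
                "AF", "NSR", "PVC", "AF"]
        cm = confusion_matrix(true, pred, classes=["NSR", "AF", "PVC"])
        np.testing.assert_array_equal(cm, [[3, 1, 0], [1, 3, 0], [1, 0, 3]])
        assert cm.sum(axis=1).tolist() == [4, 4, 4]  # row sums = true counts

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["AF"], ["AF", "NSR"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class set"):
            confusion_matrix(["VT"], ["AF"])


class TestPerClassMetrics:
    def test_diagonal_matrix_all_ones(self):
        table = per_class_metrics(np.diag([3, 4, 5]), classes=list("abc"))
        for col in ["precision", "sensitivity", "specificity", "f1"]:
            np.testing.assert_allclose(table[col], 1.0)

    def test_three_class_toy_matches_hand_computation(self):
        cm = np.array([[5, 1, 0], [1, 4, 0], [0, 0, 3]])
        t = per_class_metrics(cm, classes=list("abc"))
        # class a: TP 5, FP 1, FN 1, TN 7
        assert t.loc["a", "precision"] == pytest.approx(5 / 6)
        assert t.loc["a", "sensitivity"] == pytest.approx(5 / 6)
        assert t.loc["a", "specificity"] == pytest.approx(7 / 8)
        assert t.loc["a", "f1"] == pytest.approx(5 / 6)
        # class c is perfectly separated
        assert t.loc["c", ["precision", "sensitivity", "f1"]].tolist() == [1, 1, 1]

    def test_absent_class_flagged_zero(self):
        cm = np.array([[2, 0, 0], [0, 0, 0], [0, 1, 3]])
        t = per_class_metrics(cm, classes=["a", "b", "c"])
        # class b: zero truths -> zero metrics with an explicit flag
        assert t.loc["b", "f1"] == 0.0 and t.loc["b", "sensitivity"] == 0.0
        assert bool(t.loc["b", "undefined"])
        assert not bool(t.loc["a", "undefined"])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            per_class_metrics(np.zeros((2, 3)))


class TestAggregate:
    def test_equal_counts_weighted_equals_macro(self):
        t = pd.DataFrame({"f1": [0.2, 0.4, 0.9]}, index=list("abc"))
        macro, weighted = aggregate(t, [5, 5, 5])
        assert macro["f1"] == pytest.approx(weighted["f1"])

    def test_single_nonzero_count_dominates(self):
        t = pd.DataFrame({"f1": [0.2, 0.9]}, index=list("ab"))
        _, weighted = aggregate(t, [0, 7])
        assert weighted["f1"] == pytest.approx(0.9)

    def test_all_zero_counts_rejected(self):
        t = pd.DataFrame({"f1": [0.2]}, index=["a"])
        with pytest.raises(ValueError):
            aggregate(t, [0])


class TestRocPrCurves:
    def test_perfect_separation_auc_one(self):
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        curves = roc_pr_curves(["a", "a", "b", "b"], proba, classes=["a", "b"])
        assert curves["a"]["auc_roc"] == 1.0
        assert curves["b"]["auc_pr"] == 1.0

    def test_binary_toy_matches_pair_counting_oracle(self):
        # Mann-Whitney: AUC = P(score_pos > score_neg) over all pairs
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        labels = np.array([1, 1, 0, 1, 0, 0])
        pairs = [(p, n) for p in scores[labels == 1] for n in scores[labels == 0]]
        oracle = np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                          for p, n in pairs])
        proba = np.stack([1 - scores, scores], axis=1)
        curves = roc_pr_curves(labels.tolist(), proba, classes=[0, 1])
        assert curves[1]["auc_roc"] == pytest.approx(oracle)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = rng.integers(0, 2, n).tolist()
        s = rng.random(n)
        proba = np.stack([1 - s, s], axis=1)
        curves = roc_pr_curves(labels, proba, classes=[0, 1])
        assert curves[1]["auc_roc"] == pytest.approx(0.5, abs=0.03)

    def test_degenerate_class_flagged(self):
        proba = np.array([[0.6, 0.4], [0.3, 0.7]])
        curves = roc_pr_curves(["a", "a"], proba, classes=["a", "b"])
        assert curves["b"]["degenerate"] and curves["b"]["auc_roc"] is None

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc_pr_curves(["a"], np.array([[0.9, 0.9]]), classes=["a", "b"])


class TestBuildReport:
    def test_report_is_permutation_consistent(self):
        rng = np.random.default_rng(1)
        classes = ["NSR", "AF", "PVC"]
        true = rng.choice(classes, 60).tolist()
        raw = rng.random((60, 3))
        proba = raw / raw.sum(1, keepdims=True)
        pred = [classes[j] for j in proba.argmax(1)]
        rep = build_report(true, pred, proba, classes=classes)

        perm = [2, 0, 1]
        classes_p = [classes[j] for j in perm]
        rep_p = build_report(true, pred, proba[:, perm], classes=classes_p)
        for cls in classes:
            np.testing.assert_allclose(
                rep.per_class.loc[cls].drop("undefined").astype(float),
                rep_p.per_class.loc[cls].drop("undefined").astype(float))
        np.testing.assert_allclose(rep.macro, rep_p.macro)

    def test_confusion_row_sums_equal_class_counts(self):
        true = ["AF"] * 4 + ["NSR"] * 2
        pred = ["AF", "NSR", "AF", "AF", "NSR", "AF"]
        rep = build_report(true, pred, classes=["NSR", "AF"])
        assert rep.confusion.sum(axis=1).tolist() == rep.class_counts.tolist()
        assert rep.class_counts.tolist() == [2, 4]

    def test_macro_f1_is_mean_of_per_class_f1(self):
        true = ["AF"] * 4 + ["NSR"] * 2
        pred = ["AF", "NSR", "AF", "AF", "NSR", "AF"]
        rep = build_report(true, pred, classes=["NSR", "AF"])
        assert rep.macro["f1"] == pytest.approx(rep.per_class["f1"].mean())

    def test_json_round_trip(self, tmp_path):
        rep = build_report(["AF", "NSR"], ["AF", "NSR"], classes=["NSR", "AF"])
        rep.to_json(tmp_path / "r.json")
        import json
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["classes"] == ["NSR", "AF"]
        assert data["macro"]["f1"] == 1.0
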