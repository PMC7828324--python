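"""Confusion matrix, metrics, confidence interval, ROC/AUC, baseline classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leukomorph.evaluation import (
    ShapeFeatureClassifier,
    accuracy_ci,
    compute_metrics,
    confusion_matrix,
    macro_auc,
    roc_curve,
)
from leukomorph.imagegen import CellSpec, single_cell_crop


def make_table(true, pred, scores=None, classes=None):
    df = pd.DataFrame({"true_label": true, "pred_label": pred})
    if scores is not None:
        for cls in classes:
            df["score_" + cls] = scores[cls]
    return df


def mann_whitney_auc(y_true, scores):
    """Pairwise-comparison statistic: P(random positive outscores a random
    negative), ties counted half."""
    pos = scores[y_true]
    neg = scores[~y_true]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        t = ["a", "b", "c", "a"]
        cm = confusion_matrix(make_table(t, t), ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_single_off_diagonal_cell(self):
        cm = confusion_matrix(
            make_table(["a"] * 3, ["b"] * 3), ["a", "b"]
        )
        assert cm.counts[0, 1] == 3
        assert cm.counts.sum() == 3

    def test_row_sums_are_truth_counts(self, rng):
        classes = ["a", "b", "c"]
        t = rng.choice(classes, 60)
        p = rng.choice(classes, 60)
        cm = confusion_matrix(make_table(t, p), classes)
        for i, cls in enumerate(classes):
            assert cm.counts[i].sum() == (t == cls).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(make_table(["a"], ["z"]), ["a", "b"])


class TestComputeMetrics:
    def test_diagonal_matrix_all_ones(self):
        cm = confusion_matrix(make_table(["a", "b"], ["a", "b"]), ["a", "b"])
        rep = compute_metrics(cm)
        assert rep.accuracy == 1.0
        assert (rep.per_class == 1.0).all().all()

    def test_binary_hand_arithmetic(self):
        # TP=90 FN=10 FP=30 TN=70 for class "pos"
        true = ["pos"] * 100 + ["neg"] * 100
        pred = ["pos"] * 90 + ["neg"] * 10 + ["pos"] * 30 + ["neg"] * 70
        cm = confusion_matrix(make_table(true, pred), ["pos", "neg"])
        rep = compute_metrics(cm)
        row = rep.per_class.loc["pos"]
        assert row.recall == pytest.approx(0.900)
        assert row.precision == pytest.approx(0.750)
        assert row.f1 == pytest.approx(0.818, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.800)

    def test_undefined_metrics_are_nan_not_zero(self):
        # class "c" never occurs in truth or prediction
        cm = confusion_matrix(make_table(["a", "b"], ["a", "b"]), ["a", "b", "c"])
        rep = compute_metrics(cm)
        assert np.isnan(rep.per_class.loc["c", "recall"])
        assert np.isnan(rep.per_class.loc["c", "precision"])
        assert rep.macro_recall == 1.0  # undefined entries excluded

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sample_level_oracle(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["a", "b", "c"]
        n = int(rng.integers(5, 60))
        t = rng.choice(classes, n)
        p = rng.choice(classes, n)
        cm = confusion_matrix(make_table(list(t), list(p)), classes)
        rep = compute_metrics(cm)
        assert rep.accuracy == pytest.approx(float((t == p).mean()))
        for cls in classes:
            tp = int(((t == cls) & (p == cls)).sum())
            fn = int(((t == cls) & (p != cls)).sum())
            fp = int(((t != cls) & (p == cls)).sum())
            r = rep.per_class.loc[cls]
            if tp + fn:
                assert r.recall == pytest.approx(tp / (tp + fn))
            else:
                assert np.isnan(r.recall)
            if tp + fp:
                assert r.precision == pytest.approx(tp / (tp + fp))
        assert not rep.macro_f1 > 1.0

    def test_accuracy_invariant_under_relabeling(self, rng):
        classes = ["a", "b", "c"]
        t = list(rng.choice(classes, 40))
        p = list(rng.choice(classes, 40))
        rep1 = compute_metrics(confusion_matrix(make_table(t, p), classes))
        swap = {"a": "b", "b": "c", "c": "a"}
        t2 = [swap[x] for x in t]
        p2 = [swap[x] for x in p]
        rep2 = compute_metrics(confusion_matrix(make_table(t2, p2), classes))
        assert rep1.accuracy == pytest.approx(rep2.accuracy)
        for cls in classes:
            assert rep1.per_class.loc[cls].equals(rep2.per_class.loc[swap[cls]]) or \
                np.allclose(
                    rep1.per_class.loc[cls].fillna(-1),
                    rep2.per_class.loc[swap[cls]].fillna(-1),
                )


class TestAccuracyCI:
    def test_zero_variance(self):
        ci = accuracy_ci([0.9, 0.9, 0.9])
        assert ci.halfwidth == 0.0
        assert ci.interval == (0.9, 0.9)

    def test_hand_arithmetic(self):
        ci = accuracy_ci([0.90, 0.95, 1.00])
        assert ci.mean == pytest.approx(0.95)
        assert ci.sd == pytest.approx(0.05)
        assert ci.halfwidth == pytest.approx(1.96 * 0.05 / np.sqrt(3), abs=1e-6)
        assert ci.halfwidth == pytest.approx(0.0566, abs=2e-4)

    def test_formatting_style(self):
        ci = accuracy_ci([0.941, 0.943, 0.945])
        assert str(ci).startswith("[0.943 - ")

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            accuracy_ci([0.9])


class TestROC:
    def test_perfect_separation_auc_one(self):
        df = make_table(
            ["p", "p", "n", "n"], ["p", "p", "n", "n"],
            scores={"p": [0.9, 0.8, 0.2, 0.1]}, classes=["p"],
        )
        roc = roc_curve(df, "p")
        assert roc.auc == pytest.approx(1.0)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0

    def test_constant_scores_chance_auc(self):
        df = make_table(
            ["p", "p", "n", "n"], ["p"] * 4,
            scores={"p": [0.5] * 4}, classes=["p"],
        )
        assert roc_curve(df, "p").auc == pytest.approx(0.5)

    def test_curve_monotone(self, rng):
        n = 50
        truth = rng.random(n) < 0.4
        df = make_table(
            np.where(truth, "p", "n"), ["p"] * n,
            scores={"p": rng.random(n)}, classes=["p"],
        )
        roc = roc_curve(df, "p")
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            return
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        df = make_table(
            np.where(truth, "p", "n"), ["p"] * n,
            scores={"p": scores}, classes=["p"],
        )
        assert roc_curve(df, "p").auc == pytest.approx(
            mann_whitney_auc(truth, scores)
        )

    def test_one_sided_truth_rejected(self):
        df = make_table(["p", "p"], ["p", "p"], scores={"p": [0.4, 0.6]}, classes=["p"])
        with pytest.raises(ValueError):
            roc_curve(df, "p")


@pytest.fixture(scope="module")
def tiny_sets():
    crops, labels = [], []
    for s in range(6):
        crops.append(
            single_cell_crop(
                CellSpec(center=(0, 0), shape_kind="disk", major_axis=30, minor_axis=30),
                seed=s,
            )
        )
        labels.append("lymphocyte")
    for s in range(6):
        crops.append(
            single_cell_crop(
                CellSpec(center=(0, 0), shape_kind="ellipse", major_axis=90,
                         minor_axis=80, orientation=0.3),
                seed=50 + s,
            )
        )
        labels.append("monocyte")
    return crops, labels


class TestBaselineClassifier:
    def test_identical_train_test_separable(self, tiny_sets):
        crops, labels = tiny_sets
        clf = ShapeFeatureClassifier().fit(crops, labels)
        preds = clf.predict(crops, true_labels=labels)
        assert (preds.true_label == preds.pred_label).all()

    def test_scores_normalized_per_sample(self, tiny_sets):
        crops, labels = tiny_sets
        clf = ShapeFeatureClassifier().fit(crops, labels)
        preds = clf.predict(crops)
        score_cols = [c for c in preds.columns if c.startswith("score_")]
        assert len(score_cols) == 2
        assert np.allclose(preds[score_cols].sum(axis=1), 1.0)

    def test_single_class_training_rejected(self, tiny_sets):
        crops, labels = tiny_sets
        with pytest.raises(ValueError):
            ShapeFeatureClassifier().fit(crops[:6], labels[:6])

    def test_macro_auc_on_separable_sets(self, tiny_sets):
        crops, labels = tiny_sets
        clf = ShapeFeatureClassifier().fit(crops, labels)
        preds = clf.predict(crops, true_labels=labels)
        assert macro_auc(preds, sorted(set(labels))) > 0.95
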