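"""Classifier evaluation: confusion matrix, per-class metrics, CI, ROC/AUC.

Metrics follow the usual one-vs-rest definitions — Recall = TP/(TP+FN),
Precision = TP/(TP+FP), F1 = 2PR/(P+R), Accuracy = trace/total — with a
normal-approximation 95% confidence interval over a sample of accuracy
values (μ̂ ± 1.96·σ/√n, σ the n−1 sample standard deviation) and a
threshold-sweep ROC with trapezoidal AUC.

Zero-denominator metrics are reported as NaN ("undefined") rather than 0;
macro averages skip undefined entries so a single empty class cannot drag
the average to zero silently.

A nearest-centroid classifier over shape/intensity features extracted by
the activation module gives the suite a light-weight end-to-end exercise;
it makes no claim to match a deep model's accuracy on real images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

from .activation import MeasurementError, measure_shape

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AccuracyCI",
    "ROCResult",
    "confusion_matrix",
    "compute_metrics",
    "accuracy_ci",
    "roc_curve",
    "macro_auc",
    "ShapeFeatureClassifier",
    "extract_features",
]

SCORE_PREFIX = "score_"


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k truth-vs-prediction counts; rows = truth, cols = prediction."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class MetricsReport:
    per_class: pd.DataFrame  # index = class; columns recall, precision, f1
    accuracy: float
    macro_recall: float
    macro_precision: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "per_class": {
                cls: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for cls, row in self.per_class.iterrows()
            },
        }


@dataclass(frozen=True)
class AccuracyCI:
    """μ̂ ± 1.96·σ/√n over a sample of accuracy values."""

    n: int
    mean: float
    sd: float
    halfwidth: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.halfwidth, self.mean + self.halfwidth)

    def __str__(self) -> str:  # mirrors the conventional [μ−h, μ+h] print
        return f"[{self.mean:.3f} - {self.halfwidth:.3f}, {self.mean:.3f} + {self.halfwidth:.3f}]"


@dataclass(frozen=True)
class ROCResult:
    positive_class: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _check_table(preds: pd.DataFrame) -> None:
    for col in ("true_label", "pred_label"):
        if col not in preds.columns:
            raise ValueError(f"prediction table lacks column {col!r}")


def confusion_matrix(preds: pd.DataFrame, classes: Sequence[str]) -> ConfusionMatrix:
    """counts[i, j] = number of samples with truth classes[i] predicted classes[j]."""
    _check_table(preds)
    classes = tuple(classes)
    known = set(classes)
    seen = set(preds["true_label"]) | set(preds["pred_label"])
    if not seen <= known:
        raise ValueError(f"labels outside the class list: {sorted(seen - known)}")
    counts = _sk_confusion(
        preds["true_label"], preds["pred_label"], labels=list(classes)
    )
    return ConfusionMatrix(classes=classes, counts=counts.astype(int))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest recall/precision/F1 plus overall accuracy.

    Undefined ratios (empty denominator) are NaN; macro averages are taken
    over the defined entries only.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for cls in cm.classes:
        tp, tn, fp, fn = cm.one_vs_rest(cls)
        recall = _safe_div(tp, tp + fn)
        precision = _safe_div(tp, tp + fp)
        if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
            f1 = float("nan")
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows[cls] = {"recall": recall, "precision": precision, "f1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    accuracy = float(np.trace(cm.counts) / cm.total)

    def nanmean(col: str) -> float:
        vals = per_class[col].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        macro_recall=nanmean("recall"),
        macro_precision=nanmean("precision"),
        macro_f1=nanmean("f1"),
    )


def accuracy_ci(samples: Sequence[float]) -> AccuracyCI:
    """95% normal-approximation CI over accuracy samples (n ≥ 2)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 accuracy samples")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return AccuracyCI(
        n=int(arr.size), mean=mean, sd=sd,
        halfwidth=1.96 * sd / math.sqrt(arr.size),
    )


def roc_curve(preds: pd.DataFrame, positive_class: str) -> ROCResult:
    """One-vs-rest ROC over descending score thresholds; AUC by trapezoid.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN) at each threshold; the curve is
    anchored at (0,0) and (1,1).
    """
    _check_table(preds)
    col = SCORE_PREFIX + positive_class
    if col not in preds.columns:
        raise ValueError(f"prediction table lacks score column {col!r}")
    y = (preds["true_label"] == positive_class).to_numpy()
    if y.all() or not y.any():
        raise ValueError("need both positive and negative samples")
    fpr, tpr, thr = _sk_roc(y, preds[col].to_numpy())
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        positive_class=positive_class, fpr=fpr, tpr=tpr, thresholds=thr, auc=auc
    )


def macro_auc(preds: pd.DataFrame, classes: Sequence[str]) -> float:
    """Mean one-vs-rest AUC over all classes present on both sides."""
    return float(np.mean([roc_curve(preds, c).auc for c in classes]))


# ---------------------------------------------------------------------------
# baseline shape-feature classifier

FEATURE_NAMES = (
    "area", "perimeter", "aspect_ratio", "roundness", "mean_intensity", "intensity_sd",
)


def extract_features(crop: np.ndarray) -> np.ndarray:
    """Six morphological/intensity features of a single-cell crop.

    Shape descriptors come from the activation module's measurement path;
    if no contour is found the shape entries are zero (intensity features
    remain informative).
    """
    arr = np.asarray(crop, dtype=float)
    try:
        m = measure_shape(crop)
        shape_feats = [m.area, m.perimeter, m.aspect_ratio, m.roundness]
    except MeasurementError:
        shape_feats = [0.0, 0.0, 0.0, 0.0]
    return np.array(shape_feats + [arr.mean(), arr.std()], dtype=float)


class ShapeFeatureClassifier:
    """Nearest-centroid over standardized shape/intensity features.

    Scores are inverse distances to the class centroids, normalized to sum
    to one per sample.
    """

    def __init__(self) -> None:
        self.classes_: tuple[str, ...] | None = None
        self._centroids: np.ndarray | None = None
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    def fit(
        self, crops: Sequence[np.ndarray], labels: Sequence[str]
    ) -> "ShapeFeatureClassifier":
        if len(crops) != len(labels):
            raise ValueError("crops and labels differ in length")
        classes = tuple(sorted(set(labels)))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit")
        feats = np.stack([extract_features(c) for c in crops])
        self._mu = feats.mean(axis=0)
        self._sigma = feats.std(axis=0)
        self._sigma[self._sigma == 0] = 1.0
        z = (feats - self._mu) / self._sigma
        lab = np.asarray(labels)
        self._centroids = np.stack([z[lab == c].mean(axis=0) for c in classes])
        self.classes_ = classes
        return self

    def predict(
        self,
        crops: Sequence[np.ndarray],
        true_labels: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Prediction table: true/pred labels plus one score column per class."""
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        feats = np.stack([extract_features(c) for c in crops])
        z = (feats - self._mu) / self._sigma
        d = np.linalg.norm(z[:, None, :] - self._centroids[None, :, :], axis=2)
        inv = 1.0 / (d + 1e-9)
        scores = inv / inv.sum(axis=1, keepdims=True)
        pred = [self.classes_[i] for i in np.argmin(d, axis=1)]
        table = pd.DataFrame(
            {
                "sample_id": list(sample_ids)
                if sample_ids is not None
                else [str(i) for i in range(len(crops))],
                "true_label": list(true_labels)
                if true_labels is not None
                else [""] * len(crops),
                "pred_label": pred,
            }
        )
        for j, cls in enumerate(self.classes_):
            table[SCORE_PREFIX + cls] = scores[:, j]
        return table
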