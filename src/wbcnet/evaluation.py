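"""Evaluation: stratified k-fold CV, confusion matrices, classification
metrics, and one-vs-rest ROC / Precision-Recall curves.

Cross-validation is stratified: within each class, record indices are
shuffled by the seed and dealt round-robin into k folds, so per-class fold
sizes differ by at most one and every record is tested exactly once across
the k runs.  All metrics derive from a 5x5 confusion matrix (rows = true
class, columns = predicted class): accuracy is trace/total, per-class
precision and recall are the column- and row-normalized diagonals, F1 the
harmonic mean, and macro averages are unweighted means over classes.  The
per-class "accuracy" commonly quoted for this task is per-class recall and
is reported under that name as well.

ROC curves sweep thresholds over the class-c score with ties grouped
(equal scores collapse to one operating point); ROC AUC is the trapezoid
rule over that curve, which equals the Mann-Whitney U statistic on the
score ranks.  PR AUC is step-interpolated average precision, not a
trapezoid, to avoid optimistic interpolation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (average_precision_score,
                             confusion_matrix as _sk_confusion,
                             precision_recall_curve, roc_curve)

from .dataset_io import CLASS_NAMES, LabeledDataset, canonical_class
from .models import ArchitectureSpec, BuiltModel, build_from_spec
from .training import TrainingConfig, train_model

__all__ = ["FoldPlan", "ConfusionMatrix", "MetricsReport", "stratified_kfold",
           "confusion_matrix", "classification_metrics", "ovr_curves",
           "cross_validate"]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of record indices to k folds."""

    k: int
    assignments: np.ndarray  # record index -> fold index
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class ConfusionMatrix:
    """5x5 count table; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError(f"confusion matrix must be {n}x{n}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass
class MetricsReport:
    """Per-class and macro metrics derived from one confusion matrix."""

    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class_roc_auc: dict[str, float] = field(default_factory=dict)
    per_class_pr_auc: dict[str, float] = field(default_factory=dict)
    fold: int | None = None
    zero_division_flag: bool = False

    #: per-class accuracy in the field's usage == per-class recall
    @property
    def per_class_accuracy(self) -> dict[str, float]:
        return dict(self.per_class_recall)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "per_class_roc_auc": self.per_class_roc_auc,
            "per_class_pr_auc": self.per_class_pr_auc,
            "fold": self.fold,
        }


def stratified_kfold(dataset: LabeledDataset, k: int = 10, seed: int = 0
                     ) -> FoldPlan:
    """Shuffle within each class, deal round-robin into k folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = dataset.label_indices()
    counts = dataset.counts
    for cname in CLASS_NAMES:
        if 0 < counts[cname] < k:
            raise ValueError(
                f"class {cname!r} has {counts[cname]} records, fewer than k={k}")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(dataset), -1, dtype=np.int64)
    for ci in range(len(CLASS_NAMES)):
        idx = np.flatnonzero(labels == ci)
        rng.shuffle(idx)
        for j, rec_index in enumerate(idx):
            assignments[rec_index] = j % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def _as_indices(labels) -> np.ndarray:
    index = {c: i for i, c in enumerate(CLASS_NAMES)}
    out = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            if not 0 <= lab < len(CLASS_NAMES):
                raise ValueError(f"label index {lab} out of range")
            out.append(int(lab))
        else:
            out.append(index[canonical_class(lab)])
    return np.asarray(out, dtype=np.int64)


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """counts[i][j] = number of records with true class i predicted as j."""
    t = _as_indices(true_labels)
    p = _as_indices(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    cm = _sk_confusion(t, p, labels=np.arange(len(CLASS_NAMES)))
    return ConfusionMatrix(cm)


def classification_metrics(cm: ConfusionMatrix, scores: np.ndarray | None = None,
                           true_labels=None, fold: int | None = None
                           ) -> MetricsReport:
    """Accuracy / precision / recall / F1 from a confusion matrix.

    Zero-denominator cells yield 0 with ``zero_division_flag`` set.  If
    one-vs-rest ``scores`` (n x 5) and ``true_labels`` are supplied, ROC and
    PR AUCs are filled in via :func:`ovr_curves`.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts).astype(np.float64)
    col = counts.sum(axis=0).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)
    flag = bool((col == 0).any() or (row == 0).any())
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    if bool(((denom == 0)).any()):
        flag = True
    weights = row / row.sum()
    report = MetricsReport(
        per_class_precision=dict(zip(CLASS_NAMES, prec.tolist())),
        per_class_recall=dict(zip(CLASS_NAMES, rec.tolist())),
        per_class_f1=dict(zip(CLASS_NAMES, f1.tolist())),
        accuracy=cm.accuracy,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((weights * prec).sum()),
        weighted_recall=float((weights * rec).sum()),
        weighted_f1=float((weights * f1).sum()),
        fold=fold,
        zero_division_flag=flag,
    )
    if scores is not None and true_labels is not None:
        curves = ovr_curves(scores, true_labels)
        report.per_class_roc_auc = {c: curves[c]["roc_auc"] for c in CLASS_NAMES}
        report.per_class_pr_auc = {c: curves[c]["pr_auc"] for c in CLASS_NAMES}
    return report


def ovr_curves(scores, true_labels) -> dict[str, dict]:
    """One-vs-rest ROC and PR curves with AUCs for each class.

    Returns {class: {fpr, tpr, roc_auc, precision, recall, pr_auc}}.  A
    class absent from (or filling all of) the truth gets NaN AUCs rather
    than fabricated values.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != len(CLASS_NAMES):
        raise ValueError("scores must be n x 5")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    t = _as_indices(true_labels)
    out: dict[str, dict] = {}
    for ci, cname in enumerate(CLASS_NAMES):
        binary = (t == ci).astype(np.int64)
        entry: dict = {}
        if binary.min() == binary.max():  # one-class truth: undefined
            entry = {"fpr": None, "tpr": None, "roc_auc": float("nan"),
                     "precision": None, "recall": None, "pr_auc": float("nan"),
                     "undefined": True}
        else:
            fpr, tpr, _ = roc_curve(binary, scores[:, ci])
            prec, rec, _ = precision_recall_curve(binary, scores[:, ci])
            entry = {
                "fpr": fpr, "tpr": tpr,
                "roc_auc": float(np.trapezoid(tpr, fpr)),
                "precision": prec, "recall": rec,
                "pr_auc": float(average_precision_score(binary, scores[:, ci])),
                "undefined": False,
            }
        out[cname] = entry
    return out


def cross_validate(architecture: ArchitectureSpec, dataset: LabeledDataset,
                   training_config: TrainingConfig, k: int = 10, seed: int = 0
                   ) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold CV: k independently trained models.

    Returns (per-fold reports, pooled report over all held-out predictions).
    """
    plan = stratified_kfold(dataset, k=k, seed=seed)
    y = dataset.label_indices()
    fold_reports: list[MetricsReport] = []
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    pooled_scores: list[np.ndarray] = []
    for fold in range(k):
        train_idx = plan.train_indices(fold)
        test_idx = plan.fold_indices(fold)
        model = build_from_spec(architecture, seed=seed * 1000 + fold)
        model, _ = train_model(model, dataset.subset(train_idx),
                               training_config)
        x_test = dataset.subset(test_idx).pixel_stack().astype(np.float32)
        scores = model.forward(x_test)
        pred = scores.argmax(axis=1)
        cm = confusion_matrix(y[test_idx], pred)
        fold_reports.append(classification_metrics(
            cm, scores=scores, true_labels=y[test_idx], fold=fold))
        pooled_true.extend(y[test_idx].tolist())
        pooled_pred.extend(pred.tolist())
        pooled_scores.append(scores)
    pooled_cm = confusion_matrix(pooled_true, pooled_pred)
    pooled = classification_metrics(pooled_cm,
                                    scores=np.vstack(pooled_scores),
                                    true_labels=pooled_true)
    return fold_reports, pooled
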