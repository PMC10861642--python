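"""Linear-SVM training and the confusion-matrix metric battery.

Multiclass evaluation is one-vs-rest: each class in turn is the positive,
everything else the negative, giving per-class TP/FP/FN/TN from the K x K
confusion matrix.  Headline values are the unweighted (macro) mean of the
per-class metrics, plus the pooled (micro) accuracy trace(cm)/n.

Identities that hold exactly on every confusion matrix: recall = sensitivity
= TPR; FNR = 1 - TPR; specificity = TNR = 1 - FPR; and the per-class Dice
coefficient 2TP/(2TP + FP + FN) equals the per-class F1 score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .io import FeatureTable

__all__ = [
    "SplitSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "TrainedClassifier",
    "ROCResult",
    "stratified_split",
    "fit_linear_svm",
    "predict",
    "decision_scores",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "dice_per_class",
    "roc_ovr",
    "evaluate",
    "learning_curve",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and cross-validation protocol."""

    test_fraction: float = 0.2
    folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts: rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-class (TP, FP, FN, TN) under one-vs-rest reduction."""
        tp = np.diag(self.counts).astype(np.float64)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0/0 -> 0 (undefined rate on an empty group)."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


@dataclass
class MetricsReport:
    """Per-class, macro, and micro metrics derived from a confusion matrix."""

    labels: tuple[str, ...]
    per_class: dict[str, np.ndarray]
    macro: dict[str, float]
    micro_accuracy: float
    dice: np.ndarray = field(default=None)  # type: ignore[assignment]
    dice_macro: float = float("nan")
    auc_per_class: dict[str, float] = field(default_factory=dict)
    auc_micro: float = float("nan")

    def to_dict(self) -> dict:
        out = {
            "labels": list(self.labels),
            "per_class": {k: list(map(float, v)) for k, v in self.per_class.items()},
            "macro": {k: float(v) for k, v in self.macro.items()},
            "micro_accuracy": float(self.micro_accuracy),
        }
        if self.dice is not None:
            out["dice_per_class"] = list(map(float, self.dice))
            out["dice_macro"] = float(self.dice_macro)
        if self.auc_per_class:
            out["auc_per_class"] = {k: float(v) for k, v in self.auc_per_class.items()}
            out["auc_micro"] = float(self.auc_micro)
        return out


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate the full metric battery on a confusion matrix.

    Per class (one-vs-rest): accuracy (TP+TN)/n, precision TP/(TP+FP),
    recall TP/(TP+FN), F1, sensitivity, specificity, TPR, FPR, FNR, TNR,
    and Dice 2TP/(2TP+FP+FN).  Macro values are unweighted means over
    classes; micro accuracy is trace(cm)/n.
    """
    tp, fp, fn, tn = cm.one_vs_rest()
    total = float(cm.total)
    if total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    tpr = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, fp + tn)
    # complements computed structurally so FNR = 1 - TPR and TNR = 1 - FPR
    # hold even for a class with no positives (0/0 -> 0 convention above)
    tnr = 1.0 - fpr
    fnr = 1.0 - tpr
    precision = _safe_div(tp, tp + fp)
    recall = tpr
    f1 = _safe_div(2 * precision * recall, precision + recall)
    per_class = {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "sensitivity": tpr,
        "specificity": tnr,
        "tpr": tpr,
        "fpr": fpr,
        "fnr": fnr,
        "tnr": tnr,
    }
    macro = {k: float(v.mean()) for k, v in per_class.items()}
    dice, dice_macro = dice_per_class(cm)
    return MetricsReport(
        labels=cm.labels,
        per_class=per_class,
        macro=macro,
        micro_accuracy=float(np.trace(cm.counts) / total),
        dice=dice,
        dice_macro=dice_macro,
    )


def dice_per_class(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class Dice coefficient 2TP/(2TP+FP+FN) and its macro mean.

    A class absent from both truth and prediction (2TP+FP+FN = 0) is a
    vacuous perfect match; its Dice is defined as 1 and a warning is raised.
    """
    tp, fp, fn, _ = cm.one_vs_rest()
    denom = 2 * tp + fp + fn
    dice = np.ones_like(tp, dtype=np.float64)
    defined = denom > 0
    dice[defined] = 2 * tp[defined] / denom[defined]
    if not defined.all():
        empty = [cm.labels[k] for k in np.flatnonzero(~defined)]
        warnings.warn(f"Dice undefined (empty-vs-empty) for classes {empty}; reported as 1")
    return dice, float(dice.mean())


def stratified_split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/test partition preserving class proportions."""
    labels = np.asarray(table.labels)
    _, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to split")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    return table.subset(sorted(train_idx)), table.subset(sorted(test_idx))


@dataclass(frozen=True)
class TrainedClassifier:
    """A fitted one-vs-rest linear SVM with its standardization parameters.

    Features are z-scored with train-set statistics before the linear
    decision functions; prediction is fully determined by the stored
    parameters.
    """

    classes: tuple[str, ...]
    coef: np.ndarray
    intercept: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    column_names: tuple[str, ...]

    def _check_layout(self, table: FeatureTable) -> None:
        if tuple(table.column_names) != self.column_names:
            raise ValueError("feature table layout does not match the trained model")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """(n, K) decision scores; binary models are expanded to two columns."""
        Z = (np.asarray(X, dtype=np.float64) - self.feature_mean) / self.feature_std
        scores = Z @ self.coef.T + self.intercept
        if len(self.classes) == 2 and scores.shape[1] == 1:
            scores = np.hstack([-scores, scores])
        return scores

    def predict_values(self, X: np.ndarray) -> list[str]:
        scores = self.decision_function(X)
        return [self.classes[k] for k in scores.argmax(axis=1)]


def fit_linear_svm(
    train: FeatureTable, C: float = 1.0, seed: int = 0
) -> TrainedClassifier:
    """Fit a one-vs-rest linear-kernel SVM (squared hinge) on z-scored features.

    Feature blocks span several orders of magnitude (raw GLCM contrast vs.
    LBP frequencies), so each column is standardized with train-set mean and
    standard deviation; constant columns get unit scale.
    """
    labels = np.asarray(train.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    X = train.values
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(Z, labels)
    coef = np.atleast_2d(svm.coef_)
    intercept = np.atleast_1d(svm.intercept_)
    return TrainedClassifier(
        classes=tuple(str(c) for c in svm.classes_),
        coef=coef,
        intercept=intercept,
        feature_mean=mean,
        feature_std=std,
        column_names=tuple(train.column_names),
    )


def predict(model: TrainedClassifier, table: FeatureTable) -> list[str]:
    model._check_layout(table)
    return model.predict_values(table.values)


def decision_scores(model: TrainedClassifier, table: FeatureTable) -> np.ndarray:
    model._check_layout(table)
    return model.decision_function(table.values)


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    counts = _sk_confusion(list(y_true), list(y_pred), labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


@dataclass
class ROCResult:
    """One-vs-rest ROC curves and trapezoidal AUC values."""

    labels: tuple[str, ...]
    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # fpr, tpr, thresholds
    auc_per_class: dict[str, float]
    auc_macro: float
    auc_micro: float


def roc_ovr(scores: np.ndarray, y_true: Sequence[str], labels: Sequence[str]) -> ROCResult:
    """One-vs-rest ROC analysis from per-class decision scores.

    Each class k sweeps thresholds over its score column against the binary
    truth (label == k); AUC is the trapezoidal area.  The micro-average pools
    all (score, binary label) pairs across classes into one curve.  A class
    with no positives or no negatives has undefined AUC and is omitted from
    the macro mean with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("ROC analysis requires finite scores")
    y_true = np.asarray(y_true)
    labels = tuple(labels)
    if scores.shape != (len(y_true), len(labels)):
        raise ValueError(
            f"scores shape {scores.shape} does not match {len(y_true)} samples x {len(labels)} classes"
        )
    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    aucs: dict[str, float] = {}
    pooled_truth: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    for k, label in enumerate(labels):
        binary = (y_true == label).astype(int)
        pooled_truth.append(binary)
        pooled_scores.append(scores[:, k])
        if binary.sum() == 0 or binary.sum() == len(binary):
            warnings.warn(f"class {label!r} has no positives or no negatives; AUC undefined")
            aucs[label] = float("nan")
            continue
        fpr, tpr, thr = _sk_roc_curve(binary, scores[:, k], drop_intermediate=False)
        curves[label] = (fpr, tpr, thr)
        aucs[label] = float(_trapezoid_auc(fpr, tpr))
    defined = [v for v in aucs.values() if np.isfinite(v)]
    macro = float(np.mean(defined)) if defined else float("nan")
    all_truth = np.concatenate(pooled_truth)
    all_scores = np.concatenate(pooled_scores)
    if 0 < all_truth.sum() < len(all_truth):
        fpr_m, tpr_m, _ = _sk_roc_curve(all_truth, all_scores, drop_intermediate=False)
        micro = float(_trapezoid_auc(fpr_m, tpr_m))
    else:
        micro = float("nan")
    return ROCResult(
        labels=labels, curves=curves, auc_per_class=aucs, auc_macro=macro, auc_micro=micro
    )


def evaluate(
    model: TrainedClassifier, test: FeatureTable
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Score a held-out table: confusion matrix, metric battery, Dice, ROC/AUC."""
    model._check_layout(test)
    y_pred = model.predict_values(test.values)
    cm = confusion_from_predictions(test.labels, y_pred, model.classes)
    report = metrics_from_confusion(cm)
    roc = roc_ovr(model.decision_function(test.values), test.labels, model.classes)
    report.auc_per_class = roc.auc_per_class
    report.auc_micro = roc.auc_micro
    return cm, report


def _accuracy(y_true: np.ndarray, y_pred: Sequence[str]) -> float:
    return float(np.mean(np.asarray(y_pred) == y_true))


def learning_curve(
    table: FeatureTable,
    sizes: Sequence[float],
    spec: SplitSpec,
    C: float = 1.0,
) -> dict[float, dict[str, float]]:
    """K-fold cross-validated accuracy at increasing training-set fractions.

    For each fraction, each CV fold's training portion is stratified-
    subsampled to that fraction, the SVM refit, and accuracy measured on the
    subsample (train score) and on the held-out fold (validation score).
    Fractions leaving some class without a sample are skipped with a warning.
    Returns {size: {train_mean, train_sd, val_mean, val_sd}}.
    """
    for s in sizes:
        if not 0.0 < s <= 1.0:
            raise ValueError(f"sizes must lie in (0, 1], got {s}")
    labels = np.asarray(table.labels)
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(table.values, labels))
    results: dict[float, dict[str, float]] = {}
    rng = np.random.default_rng(spec.seed)
    for size in sizes:
        train_scores, val_scores = [], []
        skipped = False
        for train_idx, val_idx in folds:
            sub_idx: list[int] = []
            fold_labels = labels[train_idx]
            for cls in np.unique(fold_labels):
                cls_idx = train_idx[fold_labels == cls]
                n_take = int(round(size * len(cls_idx)))
                if n_take < 1:
                    skipped = True
                    break
                chosen = rng.choice(cls_idx, size=n_take, replace=False)
                sub_idx.extend(chosen.tolist())
            if skipped:
                break
            sub = table.subset(sorted(sub_idx))
            if len(set(sub.labels)) < 2:
                skipped = True
                break
            model = fit_linear_svm(sub, C=C, seed=spec.seed)
            train_scores.append(_accuracy(np.asarray(sub.labels), model.predict_values(sub.values)))
            val = table.subset(val_idx.tolist())
            val_scores.append(_accuracy(np.asarray(val.labels), model.predict_values(val.values)))
        if skipped:
            warnings.warn(f"size {size} leaves a class empty in some fold; skipped")
            continue
        results[float(size)] = {
            "train_mean": float(np.mean(train_scores)),
            "train_sd": float(np.std(train_scores)),
            "val_mean": float(np.mean(val_scores)),
            "val_sd": float(np.std(val_scores)),
        }
    return results
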