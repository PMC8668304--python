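"""Data partitioning, cross-validation schemes, confusion matrices and
classification/segmentation metrics.

The 70/10/20 split uses round-half-up for the train and test counts and
assigns the remainder to validation; this convention reproduces the
published partition tables exactly (1425 → 998/142/285, 1675 → 1173/167/335,
2470 → 1729/247/494).  Metrics are expressed as percentages:

    accuracy    = (TP + TN) / (TP + FN + TN + FP) x 100
    sensitivity = TP / (TP + FN)                  (a.k.a. recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    dice / F1   = 2·precision·recall / (precision + recall)

Zero-denominator metrics are reported as NaN with a warning, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import SizeError, TumorsegError


def _round_half_up_tenths(n: int, tenths: int) -> int:
    """round-half-up(n * tenths/10) in exact integer arithmetic."""
    return (n * tenths + 5) // 10


@dataclass
class DatasetSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple = (0.7, 0.1, 0.2)
    seed: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.val_idx), len(self.test_idx)


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise TumorsegError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "dice": self.dice,
        }


def split_counts(n: int) -> tuple[int, int, int]:
    """(train, val, test) counts for the 70/10/20 convention."""
    train = _round_half_up_tenths(n, 7)
    test = _round_half_up_tenths(n, 2)
    val = n - train - test
    return train, val, test


def split_dataset(n: int, seed: int = 0) -> DatasetSplit:
    """Randomized 70/10/20 index split with deterministic counts."""
    if n < 10:
        raise TumorsegError(f"need n >= 10 to split 70/10/20, got {n}")
    train, val, test = split_counts(n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DatasetSplit(
        train_idx=perm[:train],
        val_idx=perm[train : train + val],
        test_idx=perm[train + val :],
        seed=seed,
    )


def confusion(y_true, y_pred, positive) -> ConfusionMatrix:
    """2x2 confusion counts with an explicit positive class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise TumorsegError("y_true and y_pred must have equal length")
    domain = set(y_true) | set(y_pred)
    if len(domain) > 2:
        raise TumorsegError(f"binary confusion needs <= 2 classes, got {sorted(map(str, domain))}")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=tn)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def dice_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as the inputs)."""
    if precision + recall == 0:
        warnings.warn("dice undefined (precision + recall = 0); reporting NaN", stacklevel=2)
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and dice, in percent."""
    if cm.total == 0:
        raise TumorsegError("all-zero confusion matrix")
    accuracy = _safe_ratio(cm.TP + cm.TN, cm.total, "accuracy") * 100.0
    sensitivity = _safe_ratio(cm.TP, cm.TP + cm.FN, "sensitivity") * 100.0
    specificity = _safe_ratio(cm.TN, cm.TN + cm.FP, "specificity") * 100.0
    precision = _safe_ratio(cm.TP, cm.TP + cm.FP, "precision") * 100.0
    dice = dice_from_precision_recall(precision, sensitivity)
    return MetricsReport(accuracy, sensitivity, specificity, precision, dice)


def segmentation_confusion(
    pred_mask: np.ndarray, true_mask: np.ndarray, ignore_label: int = 255
) -> ConfusionMatrix:
    """Pixel-wise confusion counts (positive class = 1), ignoring a label."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise SizeError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    valid = true != ignore_label
    p = pred[valid] == 1
    t = true[valid] == 1
    return ConfusionMatrix(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray, ignore_label: int = 255) -> float:
    """Pixel overlap dice 2TP/(2TP+FP+FN) on the 0-1 scale (NaN if both empty)."""
    cm = segmentation_confusion(pred_mask, true_mask, ignore_label)
    den = 2 * cm.TP + cm.FP + cm.FN
    if den == 0:
        return float("nan")
    return 2.0 * cm.TP / den


def kfold_record(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Record-wise (stratified) k-fold assignment.

    Returns an array of fold ids aligned with ``labels``; per-fold class
    counts differ by at most 1.  Classes with fewer than ``k`` members get a
    best-effort assignment with a warning.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise TumorsegError(f"k={k} exceeds number of items {n}")
    _, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        warnings.warn("some class has fewer members than folds; stratification is best-effort")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        folds[test_idx] = fold_id
    return folds


def kfold_subject(subject_ids, k: int = 10, seed: int = 0) -> np.ndarray:
    """Subject-wise k-fold assignment: a subject never spans folds.

    Subjects are assigned greedily, largest first, to the currently
    smallest fold; ties among subjects of equal size are broken by a seeded
    shuffle.  Fold-size spread is bounded by the largest subject size.
    """
    subject_ids = np.asarray(subject_ids)
    subjects, inverse, sizes = np.unique(subject_ids, return_inverse=True, return_counts=True)
    if len(subjects) < k:
        raise TumorsegError(f"need >= {k} distinct subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    order = order[np.argsort(-sizes[order], kind="stable")]  # largest first, seeded ties
    fold_of_subject = np.empty(len(subjects), dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for s in order:
        target = int(fold_sizes.argmin())
        fold_of_subject[s] = target
        fold_sizes[target] += sizes[s]
    return fold_of_subject[inverse]
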