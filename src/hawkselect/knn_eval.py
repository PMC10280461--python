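"""Manhattan-distance K-nearest-neighbour fitness and confusion metrics.

The wrapper search scores every candidate feature mask by the k-fold
cross-validated accuracy of a KNN classifier restricted to the selected
columns. Because the search compares fitness values for strict improvement,
prediction must be a deterministic function of (data, mask, fold assignment);
the classifier here therefore fixes explicit tie-break rules instead of
delegating to a library whose tie behaviour is unspecified:

* distance ties at the k-th neighbour boundary keep the lower training-row
  index (stable sort);
* vote ties between classes go to the class with the smaller summed distance
  among its voting neighbours, then to the lower label value.

Features are used on their raw numeric/integer-coded scale — no
standardisation — matching L1 distance on coded clinical columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset_io import FoldAssignment, TabularDataset, make_folds

__all__ = [
    "KNNConfig",
    "ConfusionCounts",
    "MetricSet",
    "manhattan_distance",
    "knn_predict",
    "CrossValidatedKNN",
    "cv_accuracy",
    "cv_confusion",
    "compute_metrics",
]


@dataclass
class KNNConfig:
    """Neighbour count and cross-validation fold count."""

    k: int = 5
    folds: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts; the positive class is the rare outcome."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """Accuracy, MCC, precision and recall derived from confusion counts.

    ``precision`` / ``recall`` are ``None`` when their denominator is zero
    (no predicted / no actual positives): an explicit undefined flag rather
    than a silent 0. MCC with a zero denominator is reported as 0.
    """

    accuracy: float
    mcc: float
    precision: float | None
    recall: float | None


def manhattan_distance(a, b) -> float:
    """L1 distance: the sum of absolute coordinate differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def _vote(labels: np.ndarray, dists: np.ndarray) -> int:
    """Majority vote with deterministic tie-breaks.

    Ties between classes are resolved by the smaller summed distance of the
    tied class's voting neighbours, then by the lower label value.
    """
    classes, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = classes[counts == best]
    if len(tied) == 1:
        return int(tied[0])
    sums = [(dists[labels == c].sum(), c) for c in tied]
    sums.sort()
    return int(sums[0][1])


def knn_predict(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    k: int = 5,
) -> int:
    """Label of `query` by majority vote of its k nearest training rows (L1).

    k larger than the training set truncates to all available rows.
    """
    train_values = np.atleast_2d(np.asarray(train_values, dtype=float))
    if train_values.shape[0] == 0:
        raise ValueError("empty training set")
    d = np.abs(train_values - np.asarray(query, dtype=float)).sum(axis=1)
    k_eff = min(k, len(d))
    order = np.argsort(d, kind="stable")[:k_eff]
    return _vote(np.asarray(train_labels)[order], d[order])


def _predict_fold(
    train_X: np.ndarray, train_y: np.ndarray, val_X: np.ndarray, k: int
) -> np.ndarray:
    """Vectorised binary-vote prediction for one validation fold."""
    D = cdist(val_X, train_X, metric="cityblock")
    k_eff = min(k, train_X.shape[0])
    order = np.argsort(D, axis=1, kind="stable")[:, :k_eff]
    neigh_labels = train_y[order]
    pos = neigh_labels.sum(axis=1)
    pred = (2 * pos > k_eff).astype(int)
    # rows with an exact vote tie fall back to the full tie-break rule
    tied = np.flatnonzero(2 * pos == k_eff)
    for i in tied:
        pred[i] = _vote(neigh_labels[i], D[i, order[i]])
    return pred


class CrossValidatedKNN:
    """Reusable cross-validated KNN fitness for a fixed dataset and folds.

    The fold assignment is drawn once; every mask scored by the same instance
    sees the same partition, so fitness is a pure function of the mask and
    "strictly better" comparisons in the search are well defined.
    """

    def __init__(
        self,
        ds: TabularDataset,
        cfg: KNNConfig | None = None,
        fold_seed: int = 0,
        fold_assignment: FoldAssignment | None = None,
    ):
        self.cfg = cfg or KNNConfig()
        self.X = np.ascontiguousarray(ds.values, dtype=float)
        self.y = np.asarray(ds.labels, dtype=int)
        if fold_assignment is None:
            fold_assignment = make_folds(ds.n_rows, self.cfg.folds, fold_seed)
        self.folds = fold_assignment
        self._splits = [fold_assignment.split(f) for f in range(fold_assignment.folds)]

    def _check_mask(self, mask) -> np.ndarray:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.X.shape[1],):
            raise ValueError("mask length must equal n_features")
        if not mask.any():
            raise ValueError("mask must select at least one feature")
        return mask

    def accuracy(self, mask) -> float:
        """Mean over folds of the held-out fold's fraction correct."""
        mask = self._check_mask(mask)
        Xm = self.X[:, mask]
        accs = []
        for train_idx, val_idx in self._splits:
            pred = _predict_fold(Xm[train_idx], self.y[train_idx], Xm[val_idx], self.cfg.k)
            accs.append(float((pred == self.y[val_idx]).mean()))
        return float(np.mean(accs))

    __call__ = accuracy

    def confusion(self, mask) -> ConfusionCounts:
        """Confusion counts pooled over every row's held-out prediction."""
        mask = self._check_mask(mask)
        Xm = self.X[:, mask]
        tp = tn = fp = fn = 0
        for train_idx, val_idx in self._splits:
            pred = _predict_fold(Xm[train_idx], self.y[train_idx], Xm[val_idx], self.cfg.k)
            truth = self.y[val_idx]
            tp += int(((pred == 1) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def cv_accuracy(
    ds: TabularDataset,
    mask,
    cfg: KNNConfig | None = None,
    fold_seed: int = 0,
    fold_assignment: FoldAssignment | None = None,
) -> float:
    """One-shot cross-validated accuracy of a feature mask."""
    return CrossValidatedKNN(ds, cfg, fold_seed, fold_assignment).accuracy(mask)


def cv_confusion(
    ds: TabularDataset,
    mask,
    cfg: KNNConfig | None = None,
    fold_seed: int = 0,
    fold_assignment: FoldAssignment | None = None,
) -> ConfusionCounts:
    """One-shot CV-pooled confusion counts of a feature mask."""
    return CrossValidatedKNN(ds, cfg, fold_seed, fold_assignment).confusion(mask)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, Matthews correlation, precision and recall from counts.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), reported as 0
    when any factor of the denominator vanishes.
    """
    if c.total == 0:
        raise ValueError("no scored rows")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(accuracy=accuracy, mcc=mcc, precision=precision, recall=recall)
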