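"""Random-forest cross-validation, evaluation metrics, precision-recall curves.

The forest itself is delegated to scikit-learn behind this module's
interface; its parameters are pinned explicitly in :class:`RFConfig`
(100 trees, unlimited depth, seed 1) so every run is reproducible.  A
sample's score is the fraction of trees voting for the interaction-site
class; the decision threshold k (default 0.5) turns scores into a
confusion matrix, from which sensitivity (recall), precision,
specificity, accuracy and the Matthews correlation coefficient are
computed:

    Sn  = TP / (TP + FN)
    Pr  = TP / (TP + FP)
    Sp  = TN / (TN + FP)
    Ac  = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .encoding import FeatureMatrix


@dataclasses.dataclass(frozen=True)
class RFConfig:
    """Pinned random-forest parameters; recorded in every output header."""

    n_trees: int = 100
    max_depth: int = 0  # 0 = unlimited
    seed: int = 1
    vote_threshold: float = 0.5  # k

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.vote_threshold < 1.0:
            raise ValueError("vote threshold k must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
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


@dataclasses.dataclass(frozen=True)
class Metrics:
    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    mcc: float


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Sn, Pr, Sp, Ac and MCC from a confusion matrix.

    A zero denominator yields MCC 0; for the ratio metrics it yields 0
    with a warning (the quantity is undefined on that table).
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")

    def ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    sn = ratio(c.tp, c.tp + c.fn, "sensitivity")
    pr = ratio(c.tp, c.tp + c.fp, "precision")
    sp = ratio(c.tn, c.tn + c.fp, "specificity")
    ac = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(sn, pr, sp, ac, mcc)


def stratified_folds(
    y: np.ndarray, folds: int = 10, cv_seed: int = 1
) -> list[tuple[np.ndarray, np.ndarray]]:
    """A reproducible stratified fold partition (train_idx, test_idx)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for cross-validation")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples, fewer than "
            f"{folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _vote_scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class, per sample."""
    pos_idx = int(np.flatnonzero(clf.classes_ == 1)[0])
    votes = np.zeros(X.shape[0])
    for est in clf.estimators_:
        votes += est.predict(X) == pos_idx
    return votes / len(clf.estimators_)


def cross_validate(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    rf: RFConfig = RFConfig(),
    folds: int = 10,
    cv_seed: int = 1,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[ConfusionCounts, np.ndarray]:
    """K-fold cross-validation; every sample scored by a model not trained on it.

    Returns the confusion counts at threshold k and the per-sample vote
    scores.  ``splits`` lets a caller reuse one fold partition across
    many feature subsets (as the incremental selection loop does).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    if splits is None:
        splits = stratified_folds(y, folds=folds, cv_seed=cv_seed)
    scores = np.full(len(y), np.nan)
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold contains a single class")
        clf = RandomForestClassifier(
            n_estimators=rf.n_trees,
            max_depth=None if rf.max_depth == 0 else rf.max_depth,
            random_state=rf.seed,
            n_jobs=1,
        )
        clf.fit(values[train_idx], y[train_idx])
        scores[test_idx] = _vote_scores(clf, values[test_idx])
    if np.isnan(scores).any():
        raise ValueError("fold partition does not cover all samples")
    predicted = scores >= rf.vote_threshold
    actual = y == 1
    counts = ConfusionCounts(
        tp=int(np.sum(predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
    )
    return counts, scores


def precision_recall_curve(
    scores: np.ndarray, labels: np.ndarray
) -> list[tuple[float, float]]:
    """(recall, precision) points, one per distinct score threshold.

    At each threshold t a sample is called positive when score >= t;
    the point is computed from the resulting confusion matrix.  Points
    are returned sorted by recall.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    actual = labels == 1
    points = []
    for t in np.unique(scores):
        predicted = scores >= t
        c = ConfusionCounts(
            tp=int(np.sum(predicted & actual)),
            tn=int(np.sum(~predicted & ~actual)),
            fp=int(np.sum(predicted & ~actual)),
            fn=int(np.sum(~predicted & actual)),
        )
        m = compute_metrics(c)
        points.append((m.sensitivity, m.precision))
    points.sort()
    return points
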