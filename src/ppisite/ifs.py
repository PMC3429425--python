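"""Incremental feature selection over a ranked feature list.

Starting from an mRMR (or MaxRel) ranking, nested feature subsets
S_i = {f_1 ... f_(i*l)} are formed by adding l features at a time from
higher to lower rank, giving ceil(N/l) subsets for N ranked features
(the last subset is truncated at N so every feature is evaluated).
Each subset is scored by one 10-fold cross-validation of the random
forest; the optimal subset is the one maximizing MCC, with ties broken
toward the smaller subset.  The same fold partition is reused for every
subset size so the IFS curve is comparable across i.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classifier_eval import RFConfig, compute_metrics, cross_validate, stratified_folds
from .encoding import FeatureMatrix
from .mrmr import RankedFeatureList


@dataclasses.dataclass(frozen=True)
class IFSRecord:
    """Cross-validated metrics for the subset of the i top-ranked features."""

    i: int
    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    mcc: float


@dataclasses.dataclass(frozen=True)
class IFSResult:
    table: tuple[IFSRecord, ...]
    optimal_size: int
    optimal_features: tuple[str, ...]
    optimal_mcc: float


def subset_sizes(n_features: int, l: int) -> list[int]:
    """The evaluated subset sizes: l, 2l, ..., truncated to end at N."""
    if l < 1:
        raise ValueError("step l must be >= 1")
    if l > n_features:
        raise ValueError(f"step l={l} exceeds feature count {n_features}")
    sizes = list(range(l, n_features + 1, l))
    if sizes[-1] != n_features:
        sizes.append(n_features)
    return sizes


def select_optimal(table: list[IFSRecord] | tuple[IFSRecord, ...]) -> tuple[int, float]:
    """Smallest subset size attaining the maximum MCC."""
    if not table:
        raise ValueError("empty IFS table")
    best = max(table, key=lambda r: (r.mcc, -r.i))
    return best.i, best.mcc


def run_ifs(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    ranking: RankedFeatureList,
    l: int = 1,
    folds: int = 10,
    cv_seed: int = 1,
    rf: RFConfig = RFConfig(),
) -> IFSResult:
    """Evaluate every nested prefix of ``ranking`` and pick the MCC optimum.

    ``ranking`` must cover all columns of X exactly once.  The fold
    partition is drawn once from ``cv_seed`` and shared by all subset
    sizes; with fixed seeds the whole procedure is reproducible.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = values.shape[1]
    cols = ranking.column_order()
    if sorted(cols) != list(range(n_features)):
        raise ValueError(
            f"ranking covers {len(cols)} columns; the matrix has "
            f"{n_features} — every column must appear exactly once"
        )
    splits = stratified_folds(y, folds=folds, cv_seed=cv_seed)
    records: list[IFSRecord] = []
    for size in subset_sizes(n_features, l):
        subset = cols[:size]
        counts, _ = cross_validate(values[:, subset], y, rf=rf, splits=splits)
        m = compute_metrics(counts)
        records.append(
            IFSRecord(size, m.sensitivity, m.precision, m.specificity,
                      m.accuracy, m.mcc)
        )
    optimal_size, optimal_mcc = select_optimal(records)
    names = tuple(e.name for e in ranking.entries[:optimal_size])
    return IFSResult(tuple(records), optimal_size, names, optimal_mcc)
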