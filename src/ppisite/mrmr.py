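"""Feature ranking by mutual information: MaxRel and mRMR.

Relevance of a feature to the class, and redundancy between features,
are both measured by plug-in mutual information (in bits) on discretized
feature vectors.  Continuous features are coded into three states at
mean +/- one standard deviation; class labels are used as-is.  MaxRel
ranks features by relevance alone; mRMR selects greedily, each round
picking the candidate maximizing relevance minus mean redundancy with
the already-selected set (difference form; a quotient form is available).
The selection-round index h records when each feature was picked — a
smaller h means a better relevance/redundancy trade-off.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .encoding import FeatureMatrix

_LOG2 = np.log(2.0)


@dataclasses.dataclass(frozen=True)
class DiscreteVector:
    """An integer-coded sample vector over a small alphabet."""

    values: np.ndarray  # int codes
    alphabet_size: int

    def __post_init__(self) -> None:
        if self.alphabet_size < 1:
            raise ValueError("alphabet size must be >= 1")


@dataclasses.dataclass(frozen=True)
class RankedFeature:
    h: int  # selection round, 1-based
    column_index: int
    name: str
    score: float  # relevance (MaxRel) or selection-round objective (mRMR)


@dataclasses.dataclass(frozen=True)
class RankedFeatureList:
    entries: tuple[RankedFeature, ...]
    mode: str  # "MaxRel" or "mRMR"

    def __post_init__(self) -> None:
        hs = [e.h for e in self.entries]
        if hs != list(range(1, len(hs) + 1)):
            raise ValueError("selection rounds h must run 1..N")
        cols = [e.column_index for e in self.entries]
        if len(set(cols)) != len(cols):
            raise ValueError("each column may appear exactly once")

    def column_order(self) -> list[int]:
        return [e.column_index for e in self.entries]


def discretize(x: Sequence[float] | np.ndarray) -> DiscreteVector:
    """Code a real vector into 3 states at mean +/- one standard deviation.

    value < mu - sigma -> -1;  mu - sigma <= value < mu + sigma -> 0;
    value >= mu + sigma -> +1.  A constant vector (sigma = 0) codes to
    all zeros with a one-letter alphabet.  sigma is the population
    standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("discretize expects a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("discretize: input contains NaN or Inf")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0.0:
        return DiscreteVector(np.zeros(x.size, dtype=np.int8), 1)
    codes = np.zeros(x.size, dtype=np.int8)
    codes[x < mu - sigma] = -1
    codes[x >= mu + sigma] = 1
    return DiscreteVector(codes, 3)


def _as_codes(v: DiscreteVector | np.ndarray) -> np.ndarray:
    """Map a discrete vector to contiguous non-negative codes."""
    values = v.values if isinstance(v, DiscreteVector) else np.asarray(v)
    _, codes = np.unique(values, return_inverse=True)
    return codes


def _mi_from_joint(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a joint count table."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty joint table")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px * py))
    mi = float(np.nansum(terms)) / _LOG2
    return max(mi, 0.0)  # clamp rounding noise; plug-in MI is non-negative


def mutual_information(x: DiscreteVector, y: DiscreteVector) -> float:
    """Plug-in MI estimate I(x; y) in bits over the empirical joint."""
    xv, yv = x.values, y.values
    if len(xv) != len(yv):
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) == 0:
        raise ValueError("empty vectors")
    xc = _as_codes(x)
    yc = _as_codes(y)
    kx = int(xc.max()) + 1
    ky = int(yc.max()) + 1
    counts = np.bincount(xc * ky + yc, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_joint(counts.astype(float))


def entropy(x: DiscreteVector) -> float:
    """Plug-in entropy (bits); equals I(x; x)."""
    xc = _as_codes(x)
    p = np.bincount(xc).astype(float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum() / _LOG2)


# ---------------------------------------------------------------------------
# Matrix-level machinery
# ---------------------------------------------------------------------------

def _matrix_codes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discretize every column; return codes in {0,1,2} and a constant mask."""
    n, m = X.shape
    codes = np.zeros((n, m), dtype=np.int8)
    constant = np.zeros(m, dtype=bool)
    for j in range(m):
        dv = discretize(X[:, j])
        codes[:, j] = dv.values + 1  # {-1,0,1} -> {0,1,2}
        constant[j] = dv.alphabet_size == 1
    return codes, constant


def _label_codes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes, codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; relevance undefined")
    return codes.astype(np.int64)


def _relevance(codes: np.ndarray, y_codes: np.ndarray) -> np.ndarray:
    """I(column; class) for every column, in bits."""
    ky = int(y_codes.max()) + 1
    m = codes.shape[1]
    out = np.empty(m)
    for j in range(m):
        counts = np.bincount(
            codes[:, j].astype(np.int64) * ky + y_codes, minlength=3 * ky
        ).reshape(3, ky)
        out[j] = _mi_from_joint(counts.astype(float))
    return out


def _onehot_columns(codes: np.ndarray) -> np.ndarray:
    """Expand an n x m code matrix (states 0..2) to an n x 3m indicator matrix."""
    n, m = codes.shape
    out = np.zeros((n, 3 * m), dtype=np.float64)
    rows = np.repeat(np.arange(n), m)
    cols = (np.arange(m) * 3)[None, :] + codes.astype(np.int64)
    out[rows, cols.ravel()] = 1.0
    return out


def _mi_columns_vs(col_onehot: np.ndarray, g: np.ndarray) -> np.ndarray:
    """MI (bits) between every column of the one-hot expansion and vector ``g``.

    Joint counts computed in one pass with a one-hot matrix product.
    """
    n = col_onehot.shape[0]
    m = col_onehot.shape[1] // 3
    g_onehot = np.zeros((n, 3), dtype=np.float64)
    g_onehot[np.arange(n), g] = 1.0
    joint = (g_onehot.T @ col_onehot).reshape(3, m, 3)  # [g-state, col, col-state]
    joint = np.transpose(joint, (1, 0, 2))  # [col, 3, 3]
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px * py))
    mi = np.nansum(terms, axis=(1, 2)) / _LOG2
    return np.maximum(mi, 0.0)


def _feature_names(X: FeatureMatrix | np.ndarray) -> list[str]:
    if isinstance(X, FeatureMatrix):
        return X.feature_names
    return [f"f{j}" for j in range(np.asarray(X).shape[1])]


def _values(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def maxrel_rank(X: FeatureMatrix | np.ndarray, y: np.ndarray) -> RankedFeatureList:
    """Rank features by decreasing relevance I(f; class); ties by column index."""
    values = _values(X)
    if values.size == 0:
        raise ValueError("empty feature matrix")
    names = _feature_names(X)
    y_codes = _label_codes(y)
    codes, _ = _matrix_codes(values)
    D = _relevance(codes, y_codes)
    order = np.lexsort((np.arange(len(D)), -D))  # by -D, then ascending index
    entries = tuple(
        RankedFeature(h + 1, int(j), names[j], float(D[j]))
        for h, j in enumerate(order)
    )
    return RankedFeatureList(entries, "MaxRel")


def mrmr_rank(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    variant: str = "difference",
) -> RankedFeatureList:
    """Greedy minimum-redundancy maximum-relevance ranking over all features.

    Round 1 picks the most relevant feature; each later round picks, from
    the not-yet-selected set, the feature maximizing D - R (difference
    form) or D / R (quotient form), where D = I(f; class) and R is the
    mean MI between f and the already-selected features.  Ties break by
    ascending column index.  Zero-variance columns carry no information
    and are appended after all informative columns, in index order.
    """
    if variant not in ("difference", "quotient"):
        raise ValueError(f"unknown mRMR variant {variant!r}")
    values = _values(X)
    if values.size == 0:
        raise ValueError("empty feature matrix")
    names = _feature_names(X)
    y_codes = _label_codes(y)
    codes, constant = _matrix_codes(values)
    D = _relevance(codes, y_codes)

    m = values.shape[1]
    col_onehot = _onehot_columns(codes)
    active = np.where(~constant)[0]
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(m)
    remaining = np.ones(m, dtype=bool)
    remaining[constant] = False

    for round_no in range(len(active)):
        if round_no == 0:
            objective = D.copy()
        else:
            R = red_sum / len(selected)
            if variant == "difference":
                objective = D - R
            else:
                objective = D / np.maximum(R, 1e-12)
        objective = np.where(remaining, objective, -np.inf)
        best = int(np.argmax(objective))  # argmax takes lowest index on ties
        selected.append(best)
        scores.append(float(objective[best]))
        remaining[best] = False
        if remaining.any():
            red_sum += _mi_columns_vs(col_onehot, codes[:, best].astype(np.int64))

    for j in np.where(constant)[0]:  # degenerate columns close the ranking
        selected.append(int(j))
        scores.append(0.0)

    entries = tuple(
        RankedFeature(h + 1, j, names[j], s)
        for h, (j, s) in enumerate(zip(selected, scores))
    )
    return RankedFeatureList(entries, "mRMR")
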