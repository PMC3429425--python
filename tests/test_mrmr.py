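import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppisite import (
    DiscreteVector,
    discretize,
    entropy,
    maxrel_rank,
    mrmr_rank,
    mutual_information,
)


def vectors_from_joint(counts: dict[tuple[int, int], int]):
    """Expand a joint count table into paired discrete vectors."""
    xs, ys = [], []
    for (a, b), c in counts.items():
        xs += [a] * c
        ys += [b] * c
    kx = max(x for x, _ in counts) + 1
    ky = max(y for _, y in counts) + 1
    return (DiscreteVector(np.array(xs), kx), DiscreteVector(np.array(ys), ky))


def mi_oracle(counts: dict[tuple[int, int], int]) -> float:
    """Direct summation of the plug-in MI over a joint count table (bits)."""
    n = sum(counts.values())
    px, py = {}, {}
    for (a, b), c in counts.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    total = 0.0
    for (a, b), c in counts.items():
        if c == 0:
            continue
        p = c / n
        total += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


def greedy_mrmr_oracle(X: np.ndarray, y: np.ndarray) -> list[int]:
    """From-scratch exhaustive greedy mRMR: recompute every MI each round."""
    m = X.shape[1]
    dvs = [discretize(X[:, j]) for j in range(m)]
    ydv = DiscreteVector(np.asarray(y), 2)
    constant = [dv.alphabet_size == 1 for dv in dvs]
    D = [mutual_information(dvs[j], ydv) for j in range(m)]
    selected: list[int] = []
    remaining = [j for j in range(m) if not constant[j]]
    while remaining:
        best, best_score = None, None
        for j in remaining:
            if not selected:
                score = D[j]
            else:
                R = sum(mutual_information(dvs[j], dvs[g]) for g in selected)
                score = D[j] - R / len(selected)
            if best_score is None or score > best_score:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    selected += [j for j in range(m) if constant[j]]
    return selected


class TestDiscretize:
    def test_constant_vector(self):
        dv = discretize(np.full(10, 3.5))
        assert dv.alphabet_size == 1
        assert np.all(dv.values == 0)

    def test_three_point_example(self):
        # mu = 0, sigma = sqrt(200/3) ~ 8.165: -10 < -sigma, 10 >= sigma
        dv = discretize(np.array([-10.0, 0.0, 10.0]))
        assert list(dv.values) == [-1, 0, 1]

    def test_balanced_binary_boundary(self):
        # mu = 0.5, sigma = 0.5: 0 in [0, 1) -> 0;  1 >= 1 -> +1
        dv = discretize(np.array([0.0, 1.0, 0.0, 1.0]))
        assert list(dv.values) == [0, 1, 0, 1]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0, np.nan]))

    def test_binary_partition_preserved(self):
        # the 3-state rule never merges the two states of a binary column
        for p in (0.1, 0.3, 0.5, 0.9):
            n1 = int(p * 100)
            x = np.array([1.0] * n1 + [0.0] * (100 - n1))
            dv = discretize(x)
            assert len(np.unique(dv.values[x == 1.0])) == 1
            assert dv.values[x == 1.0][0] != dv.values[x == 0.0][0]


class TestMutualInformation:
    def test_product_table_zero(self):
        x, y = vectors_from_joint({(0, 0): 25, (0, 1): 25, (1, 0): 25, (1, 1): 25})
        assert mutual_information(x, y) == 0.0

    def test_identical_balanced_binary_one_bit(self):
        x = DiscreteVector(np.array([0, 1] * 50), 2)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_direct_summation_oracle(self):
        counts = {(0, 0): 40, (0, 1): 10, (1, 0): 10, (1, 1): 40}
        x, y = vectors_from_joint(counts)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(counts), abs=1e-12)

    def test_independent_replicates_near_zero(self):
        rng = np.random.default_rng(2)
        x = DiscreteVector(rng.integers(0, 2, 20000), 2)
        y = DiscreteVector(rng.integers(0, 2, 20000), 2)
        assert mutual_information(x, y) < 0.001

    def test_self_information_is_entropy(self):
        rng = np.random.default_rng(3)
        x = DiscreteVector(rng.integers(0, 3, 500), 3)
        assert mutual_information(x, x) == pytest.approx(entropy(x), abs=1e-12)

    def test_length_mismatch(self):
        x = DiscreteVector(np.array([0, 1]), 2)
        y = DiscreteVector(np.array([0, 1, 0]), 2)
        with pytest.raises(ValueError):
            mutual_information(x, y)

    def test_empty_rejected(self):
        x = DiscreteVector(np.array([], dtype=int), 1)
        with pytest.raises(ValueError):
            mutual_information(x, x)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        x = DiscreteVector(rng.integers(0, int(rng.integers(2, 5)), n), 4)
        y = DiscreteVector(rng.integers(0, int(rng.integers(2, 5)), n), 4)
        ixy = mutual_information(x, y)
        iyx = mutual_information(y, x)
        assert ixy >= 0.0
        assert ixy == pytest.approx(iyx, abs=1e-12)


class TestMaxRel:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 300)
        X = rng.standard_normal((300, 6))
        X[:, 3] = y.astype(float)
        ranked = maxrel_rank(X, y)
        assert ranked.entries[0].column_index == 3

    def test_duplicate_columns_adjacent_equal_scores(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 5))
        X[:, 1] = 0.8 * y + rng.standard_normal(200)
        X[:, 4] = X[:, 1]
        ranked = maxrel_rank(X, y)
        pos = {e.column_index: i for i, e in enumerate(ranked.entries)}
        assert abs(pos[1] - pos[4]) == 1
        assert pos[1] < pos[4]  # tie broken toward the lower column index
        scores = {e.column_index: e.score for e in ranked.entries}
        assert scores[1] == scores[4]

    def test_order_matches_per_column_oracle(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 250)
        X = rng.standard_normal((250, 6))
        for j, eff in enumerate([0.0, 0.5, 1.5, 0.0, 2.5, 1.0]):
            X[:, j] += eff * y
        ranked = maxrel_rank(X, y)
        ydv = DiscreteVector(y, 2)
        mis = [mutual_information(discretize(X[:, j]), ydv) for j in range(6)]
        expected = sorted(range(6), key=lambda j: (-mis[j], j))
        assert ranked.column_order() == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            maxrel_rank(np.ones((10, 3)), np.zeros(10, dtype=int))


class TestMrmr:
    def test_first_pick_agrees_with_maxrel(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 150)
        X = rng.standard_normal((150, 8)) + y[:, None] * rng.uniform(0, 2, 8)
        assert (mrmr_rank(X, y).entries[0].column_index
                == maxrel_rank(X, y).entries[0].column_index)

    def test_redundant_copy_demoted(self):
        """A: strong signal; A': exact copy; B: weak but independent."""
        rng = np.random.default_rng(8)
        n = 500
        y = rng.integers(0, 2, n)
        A = 3.0 * y + rng.standard_normal(n)
        B = 0.8 * y + rng.standard_normal(n)
        X = np.column_stack([A, A.copy(), B])
        order = mrmr_rank(X, y).column_order()
        assert order == [0, 2, 1]  # h(A)=1, h(B)=2, h(A')=3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        m = int(rng.integers(2, 9))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        X = rng.standard_normal((n, m))
        k = int(rng.integers(0, m))
        X[:, :k] += y[:, None] * rng.uniform(0.0, 2.0, k)
        assert mrmr_rank(X, y).column_order() == greedy_mrmr_oracle(X, y)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 7)) + y[:, None] * rng.uniform(0, 1.5, 7)
        perm = rng.permutation(n)
        assert mrmr_rank(X, y).column_order() == mrmr_rank(X[perm], y[perm]).column_order()
        assert maxrel_rank(X, y).column_order() == maxrel_rank(X[perm], y[perm]).column_order()

    def test_zero_variance_selected_last(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 100)
        X = rng.standard_normal((100, 5))
        X[:, 1] = 7.0  # constant
        X[:, 3] = 0.0  # constant
        order = mrmr_rank(X, y).column_order()
        assert order[-2:] == [1, 3]

    def test_every_column_once_with_round_index(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 120)
        X = rng.standard_normal((120, 9))
        ranked = mrmr_rank(X, y)
        assert sorted(ranked.column_order()) == list(range(9))
        assert [e.h for e in ranked.entries] == list(range(1, 10))
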