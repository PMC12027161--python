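"""KNN core: distances, votes, k selection, rebalancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from loadrisk import knn
from loadrisk.errors import (
    DegenerateDataError,
    InvalidParameterError,
    StratificationError,
)

finite_vec = arrays(
    np.float64, 4,
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
)


class TestDistance:
    def test_euclidean_345(self):
        assert knn.distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_manhattan(self):
        assert knn.distance((1, 2), (4, 6), "manhattan") == pytest.approx(7.0)

    def test_cosine_orthogonal_and_collinear(self):
        assert knn.distance((1, 0), (0, 1), "cosine") == pytest.approx(1.0)
        v = np.array([1.0, 2.0, 3.0])
        assert knn.distance(v, 2 * v, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_cosine_zero_vector(self):
        with pytest.raises(DegenerateDataError):
            knn.distance((0, 0), (1, 1), "cosine")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=finite_vec, b=finite_vec, c=finite_vec,
           metric=st.sampled_from(["euclidean", "manhattan"]))
    def test_metric_axioms(self, a, b, c, metric):
        dab = knn.distance(a, b, metric)
        assert dab == pytest.approx(knn.distance(b, a, metric))
        assert knn.distance(a, a, metric) == pytest.approx(0.0, abs=1e-9)
        assert dab <= knn.distance(a, c, metric) + knn.distance(c, b, metric) + 1e-9


class TestKnnProbability:
    def test_self_match(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 0])
        assert knn.knn_probability(X, y, [0.0, 0.0], k=1) == 1.0

    def test_toy_vote(self):
        # nearest three of the query are labeled case, control, case
        X = np.array([[0, 0], [1, 0], [0, 1], [9, 9], [9, 8]], dtype=float)
        y = np.array([1, 0, 1, 0, 0])
        assert knn.knn_probability(X, y, [0.2, 0.2], k=3) == pytest.approx(2 / 3)

    def test_equidistant_degenerates_to_prevalence(self):
        X = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        y = np.array([1, 0, 0, 0])
        assert knn.knn_probability(X, y, [0.0, 0.0], k=4) == pytest.approx(0.25)

    def test_k_out_of_range(self):
        X = np.zeros((3, 2))
        with pytest.raises(InvalidParameterError):
            knn.knn_probabilities(X, np.array([0, 1, 0]), X, k=4)

    def test_oracle_equivalence(self, rng):
        # brute-force reference: sort every (distance, row-index) pair
        def oracle(train_X, train_y, q, k, metric):
            def d(a, b):
                if metric == "euclidean":
                    return sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
                if metric == "manhattan":
                    return sum(abs(x - y) for x, y in zip(a, b))
                na = sum(x * x for x in a) ** 0.5
                nb = sum(x * x for x in b) ** 0.5
                return 1.0 - sum(x * y for x, y in zip(a, b)) / (na * nb)

            ranked = sorted(range(len(train_y)), key=lambda i: (d(train_X[i], q), i))
            return sum(train_y[i] for i in ranked[:k]) / k

        for _ in range(50):
            n = int(rng.integers(8, 30))
            dim = int(rng.integers(1, 6))
            X = rng.normal(size=(n, dim)) + 0.5
            y = rng.integers(0, 2, n)
            q = rng.normal(size=dim) + 0.5
            k = int(rng.choice([1, 3, 5, 7]))
            metric = str(rng.choice(knn.METRICS))
            assert knn.knn_probability(X, y, q, k, metric) == pytest.approx(
                oracle(X, y, q, k, metric), abs=1e-12
            )

    def test_permutation_invariance_generic_data(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        Q = rng.normal(size=(10, 5))
        perm = rng.permutation(40)
        a = knn.knn_probabilities(X, y, Q, k=7)
        b = knn.knn_probabilities(X[perm], y[perm], Q, k=7)
        assert np.allclose(a, b)


class TestClassify:
    def test_boundary_inclusive(self):
        assert knn.classify(0.42, 0.42) == 1
        assert knn.classify(0.41, 0.42) == 0

    def test_zero_threshold(self, rng):
        probs = rng.random(20)
        assert (knn.classify(probs, 0.0) == 1).all()


class TestSelectK:
    @staticmethod
    def two_clusters(rng, n=40):
        X = np.vstack([rng.normal(0, 0.1, (n // 2, 2)),
                       rng.normal(10, 0.1, (n // 2, 2))])
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        return X, y

    def test_separated_clusters_tie_break_to_smallest_k(self, rng):
        X, y = self.two_clusters(rng)
        best_k, table = knn.select_k(X, y, k_grid=[1, 3, 5, 7], seed=0)
        assert best_k == 1
        assert np.allclose(table["cv_score"], 1.0)

    def test_default_grid_has_60_values(self, rng):
        X = rng.normal(size=(200, 3))
        y = rng.integers(0, 2, 200)
        _, table = knn.select_k(X, y, seed=1)
        assert len(table) == 60

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([0, 1] * 30)
        a = knn.select_k(X, y, k_grid=[1, 3, 5], seed=7)
        b = knn.select_k(X, y, k_grid=[1, 3, 5], seed=7)
        assert a[0] == b[0] and a[1].equals(b[1])

    def test_single_class_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(StratificationError):
            knn.select_k(X, np.zeros(10, dtype=int), seed=0)


class TestRebalance:
    def test_oversample_exact_parity_retains_all(self, rng):
        X = rng.normal(size=(100, 2))
        y = np.array([1] * 23 + [0] * 77)
        Xb, yb = knn.rebalance(X, y, "oversample", seed=3)
        assert (yb == 1).sum() == 77 and (yb == 0).sum() == 77
        rows = {tuple(r) for r in X}
        assert rows <= {tuple(r) for r in Xb}
        assert all(tuple(r) in rows for r in Xb)

    def test_subsample_exact_parity_subset(self, rng):
        X = rng.normal(size=(100, 2))
        y = np.array([1] * 23 + [0] * 77)
        Xb, yb = knn.rebalance(X, y, "subsample", seed=3)
        assert (yb == 1).sum() == 23 and (yb == 0).sum() == 23
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in Xb)

    def test_balanced_fixed_point(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        for strategy in ("oversample", "subsample", "none"):
            _, yb = knn.rebalance(X, y, strategy, seed=0)
            assert (yb == 1).sum() == (yb == 0).sum() == 5

    def test_single_class_raises(self, rng):
        with pytest.raises(DegenerateDataError):
            knn.rebalance(rng.normal(size=(5, 2)), np.ones(5, dtype=int),
                          "oversample", seed=0)


class TestSplit:
    def test_stratified_counts(self):
        y = np.array([1] * 230 + [0] * 770)
        sp = knn.split(y, test_fraction=0.30, seed=0)
        assert len(sp.test_idx) == 300
        assert abs(int(y[sp.test_idx].sum()) - 69) <= 1
        assert len(np.intersect1d(sp.train_idx, sp.test_idx)) == 0
        assert len(sp.train_idx) + len(sp.test_idx) == 1000

    def test_deterministic(self):
        y = np.array([0, 1] * 50)
        a = knn.split(y, seed=9)
        b = knn.split(y, seed=9)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            knn.split(np.array([0, 1] * 10), test_fraction=1.5)
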