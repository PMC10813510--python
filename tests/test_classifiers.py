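import math

import numpy as np
import pytest

from batscreen.classifiers import (
    KNNModel,
    MLPParams,
    TrainConfig,
    WeightOptConfig,
    ann_fit,
    ann_forward,
    ann_predict,
    best_split,
    flatten_params,
    gini_impurity,
    grow_tree,
    knn_predict,
    tree_predict,
    unflatten_params,
    wo_ann_fit,
)
from batscreen.classifiers.nn import teaching_factor, training_loss


class TestForwardPass:
    def test_all_zero_network_outputs_half(self):
        p = MLPParams([2, 2, 1],
                      [np.zeros((2, 2)), np.zeros((2, 1))],
                      [np.zeros(2), np.zeros(1)])
        assert ann_forward(p, [3.0, -1.0]) == pytest.approx(0.5)

    def test_single_linear_unit(self):
        p = MLPParams([1, 1], [np.array([[1.0]])], [np.array([0.0])])
        assert ann_forward(p, [0.0]) == pytest.approx(0.5)

    def test_hand_computed_two_layer_network(self):
        W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.0], [-2.0]])
        b2 = np.array([0.3])
        p = MLPParams([2, 2, 1], [W1, W2], [b1, b2])
        # z1 = [1.6, 0.8] (both positive so ReLU passes), z2 = 0.3
        expected = 1.0 / (1.0 + math.exp(-0.3))
        assert ann_forward(p, [1.0, 1.0]) == pytest.approx(expected, abs=1e-12)

    def test_output_strictly_inside_unit_interval(self, rng):
        p = MLPParams([3, 4, 1],
                      [rng.normal(size=(3, 4)), rng.normal(size=(4, 1))],
                      [rng.normal(size=4), rng.normal(size=1)])
        out = ann_predict(p, rng.normal(size=(50, 3)))
        assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch_rejected(self):
        p = MLPParams([2, 1], [np.zeros((2, 1))], [np.zeros(1)])
        with pytest.raises(ValueError):
            ann_forward(p, [1.0, 2.0, 3.0])


class TestGradientTraining:
    def test_separable_blobs_reach_high_accuracy(self, blobs):
        X, y = blobs
        params = ann_fit(X, y, cfg=TrainConfig(seed=0))
        acc = np.mean((ann_predict(params, X) >= 0.5) == y)
        assert acc >= 0.99

    def test_training_reduces_loss(self, blobs):
        X, y = blobs
        rng = np.random.default_rng(0)
        from batscreen.classifiers.nn import init_params

        start = training_loss(init_params([2, 15, 15, 1], rng), X, y)
        params = ann_fit(X, y, cfg=TrainConfig(epochs=20, seed=0))
        assert training_loss(params, X, y) < start

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            ann_fit(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_same_seed_gives_identical_weights(self, blobs):
        X, y = blobs
        a = ann_fit(X, y, cfg=TrainConfig(epochs=5, seed=3))
        b = ann_fit(X, y, cfg=TrainConfig(epochs=5, seed=3))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


class TestPopulationTraining:
    def test_teaching_factor_support(self):
        rng = np.random.default_rng(0)
        draws = {teaching_factor(rng) for _ in range(10_000)}
        assert draws == {1, 2}

    def test_elite_history_non_increasing(self, blobs):
        X, y = blobs
        _, history = wo_ann_fit(
            X, y, hidden=(6, 3),
            cfg=WeightOptConfig(pop_size=10, generations=20, seed=1),
        )
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_separable_blobs_accuracy(self, blobs):
        X, y = blobs
        params, _ = wo_ann_fit(
            X, y, hidden=(8, 4),
            cfg=WeightOptConfig(pop_size=20, generations=50, seed=0),
        )
        acc = np.mean((ann_predict(params, X) >= 0.5) == y)
        assert acc >= 0.95

    def test_flatten_unflatten_roundtrip(self, rng):
        from batscreen.classifiers.nn import init_params

        p = init_params([5, 7, 3, 1], rng)
        q = unflatten_params(flatten_params(p), p.layer_sizes)
        for wa, wb in zip(p.weights, q.weights):
            np.testing.assert_array_equal(wa, wb)
        for ba, bb in zip(p.biases, q.biases):
            np.testing.assert_array_equal(ba, bb)


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


def brute_force_split(X, y, min_samples_leaf=1):
    """Independent exhaustive splitter used as the oracle."""
    n = len(y)
    parent = gini_impurity(np.bincount(y, minlength=2))
    best = None
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        for lo, hi in zip(uniq, uniq[1:]):
            thr = (lo + hi) / 2.0
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            if len(left) < min_samples_leaf or len(right) < min_samples_leaf:
                continue
            score = (
                len(left) * gini_impurity(np.bincount(left, minlength=2))
                + len(right) * gini_impurity(np.bincount(right, minlength=2))
            ) / n
            gain = parent - score
            if gain > 1e-15 and (best is None or gain > best[2] + 1e-15):
                best = (j, thr, gain)
    return best


class TestDecisionTree:
    def test_simple_one_dimensional_split(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        j, thr, gain = best_split(X, y)
        assert (j, thr) == (0, 5.0)
        assert gain == pytest.approx(0.5)

    def test_constant_feature_is_unsplittable(self):
        assert best_split(np.ones((6, 1)), np.array([0, 1, 0, 1, 0, 1])) is None

    def test_agreement_with_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 25))
            X = rng.integers(0, 5, size=(n, 3)).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            ours = best_split(X, y)
            ref = brute_force_split(X, y)
            if ref is None:
                assert ours is None
            else:
                assert ours[0] == ref[0]
                assert ours[1] == pytest.approx(ref[1])
                assert ours[2] == pytest.approx(ref[2], rel=1e-10)

    def test_pure_input_yields_single_leaf(self):
        root = grow_tree(np.arange(6, dtype=float)[:, None], np.ones(6, dtype=int))
        assert root.is_leaf and root.label == 1

    def test_memorises_consistent_data(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        root = grow_tree(X, y, max_depth=50)
        np.testing.assert_array_equal(tree_predict(root, X), y)

    def test_depth_never_exceeds_limit(self, rng):
        for depth in (1, 2, 4):
            X = rng.normal(size=(60, 4))
            y = rng.integers(0, 2, size=60)
            root = grow_tree(X, y, max_depth=depth)
            assert root.depth() <= depth

    def test_leaf_tie_prefers_class_zero(self):
        root = grow_tree(np.ones((4, 1)), np.array([0, 0, 1, 1]))
        assert root.is_leaf and root.label == 0


def brute_force_knn(X_train, y_train, x, k):
    """Oracle with the same tie rules, written as explicit sorting."""
    d = [(float(np.sum((row - x) ** 2)), i) for i, row in enumerate(X_train)]
    d.sort()  # distance then training index
    votes = [y_train[i] for _, i in d[:k]]
    return 0 if votes.count(0) >= votes.count(1) else 1


class TestKNN:
    def test_single_training_point_dominates(self):
        m = KNNModel(k=1).fit(np.array([[0.0, 0.0]]), np.array([1]))
        assert knn_predict(m, [100.0, -3.0]) == 1

    def test_nearest_of_itself(self):
        X = np.array([[0.0], [1.0], [2.0]])
        m = KNNModel(k=1).fit(X, np.array([0, 1, 0]))
        assert knn_predict(m, [1.0]) == 1

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError):
            KNNModel(k=5).fit(np.zeros((3, 1)), np.array([0, 1, 0]))

    def test_agreement_with_brute_force_oracle(self, rng):
        X = rng.integers(0, 4, size=(40, 3)).astype(float)  # many distance ties
        y = rng.integers(0, 2, size=40)
        m = KNNModel(k=5).fit(X, y)
        queries = rng.integers(0, 4, size=(200, 3)).astype(float)
        ours = m.predict(queries)
        ref = [brute_force_knn(X, y, q, 5) for q in queries]
        np.testing.assert_array_equal(ours, ref)

    def test_vote_fraction_matches_prediction(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, size=30)
        m = KNNModel(k=5).fit(X, y)
        q = rng.normal(size=(20, 2))
        frac = m.vote_fractions(q)
        np.testing.assert_array_equal(m.predict(q), (frac > 0.5).astype(int))
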