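"""Honest causal forest: leaf/split primitives against brute-force
enumeration, honesty semantics, and recovery of known effect structure."""

import numpy as np
import pytest

from sortgain import HonestCausalForest, node_tau, split_score
from sortgain.forest import Tree, grow_tree, _best_split
from sortgain.overlap import EstimationError


def brute_force_best_split(X, y, t, min_leaf):
    """Independent exhaustive search over every (feature, midpoint)."""
    best = (None, np.nan, 0.0)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            score = split_score(t, y, X[:, j] <= thr, min_leaf=min_leaf)
            if np.isfinite(score) and score > best[2]:
                best = (j, thr, score)
    return best


class TestLeafAndSplitPrimitives:
    @pytest.mark.parametrize("t, y, expected", [
        ((1, 1, 0, 0), (1, 0, 0, 0), 0.5),
        ((1, 0), (1, 1), 0.0),
        ((1, 0, 1, 0), (1, 1, 1, 1), 0.0),  # constant outcomes
    ])
    def test_node_tau(self, t, y, expected):
        assert node_tau(np.array(t), np.array(y)) == pytest.approx(expected)

    def test_node_tau_single_arm_undefined(self):
        assert np.isnan(node_tau(np.ones(4), np.ones(4)))

    def test_equal_child_effects_score_zero(self):
        t = np.array([1, 0, 1, 0])
        y = np.array([1, 0, 1, 0])  # tau = 1 in both children
        left = np.array([True, True, False, False])
        assert split_score(t, y, left) == pytest.approx(0.0)

    def test_balanced_split_score_is_quarter_gap_squared(self):
        # children of equal size with tau gap d score d^2 / 4
        t = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        y = np.array([1, 0, 1, 0, 1, 1, 1, 1])  # tau_L = 1, tau_R = 0
        left = np.arange(8) < 4
        assert split_score(t, y, left) == pytest.approx(1.0 / 4)

    def test_infeasible_split_undefined(self):
        t = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        left = np.array([True, True, False, False])  # single-arm children
        assert np.isnan(split_score(t, y, left))
        assert np.isnan(split_score(t, y, np.array([1, 0, 1, 0], bool),
                                    min_leaf=3))

    @pytest.mark.parametrize("seed", range(8))
    def test_argmax_matches_bruteforce_enumeration(self, seed):
        """On small fixtures the vectorized split search must agree with
        exhaustive enumeration of every feasible (feature, threshold)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 33))
        X = np.column_stack([
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
            np.round(rng.uniform(-0.5, 0.5, n), 2),
        ])
        t = rng.integers(0, 2, n).astype(float)
        if t.min() == t.max():
            t[0] = 1 - t[0]
        y = rng.integers(0, 2, n).astype(float)
        min_leaf = int(rng.integers(1, 4))
        expected = brute_force_best_split(X, y, t, min_leaf)
        got = _best_split(X, y, t, min_leaf, np.arange(3))
        if expected[0] is None:
            assert got is None
        else:
            assert got is not None
            assert got[2] == pytest.approx(expected[2])
            # the found split realizes the optimal score
            realized = split_score(t, y, X[:, got[0]] <= got[1],
                                   min_leaf=min_leaf)
            assert realized == pytest.approx(expected[2])


class TestGrowTree:
    def _two_level_fixture(self, n=40, gap=1.0, seed=0):
        """x1 perfectly separates tau = gap (x1=1) from tau = 0."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([
            np.repeat([0, 1], n // 2), rng.integers(0, 2, n)
        ]).astype(float)
        t = np.tile([1, 0], n // 2).astype(float)
        y = (X[:, 0] * gap) * t
        return X, y, t

    def test_separating_feature_is_chosen(self):
        X, y, t = self._two_level_fixture()
        tree = grow_tree(X, y, t, X, y, t, min_leaf=5)
        assert tree.feature[0] == 0
        assert tree.threshold[0] == pytest.approx(0.5)
        leaves = tree.feature == -1
        np.testing.assert_allclose(
            np.sort(tree.tau[leaves]), [0.0, 1.0]
        )

    def test_constant_outcomes_give_single_leaf(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(30, 2)).astype(float)
        t = np.tile([1.0, 0.0], 15)
        y = np.ones(30)
        tree = grow_tree(X, y, t, X, y, t, min_leaf=2)
        assert tree.n_leaves == 1
        assert tree.tau[0] == pytest.approx(0.0)

    def test_leaf_effects_come_only_from_estimation_half(self):
        """Honesty: poisoning the split half's outcomes must not leak
        into leaf estimates, which are recomputable from the estimation
        half alone."""
        X, y, t = self._two_level_fixture(n=60)
        X_est, y_est, t_est = self._two_level_fixture(n=60, seed=3)
        poisoned = y + 100.0
        tree = grow_tree(X, poisoned, t, X_est, y_est, t_est, min_leaf=5)
        leaf_of = tree.apply(X_est)
        for node in np.flatnonzero(tree.feature == -1):
            here = leaf_of == node
            if tree.n_treated[node] >= 1 and tree.n_control[node] >= 1:
                assert tree.tau[node] == pytest.approx(
                    node_tau(t_est[here], y_est[here])
                )
                assert abs(tree.tau[node]) <= 1.0  # no poisoned scale

    def test_single_arm_estimation_leaf_is_unusable(self):
        X, y, t = self._two_level_fixture()
        # estimation half entirely treated -> every leaf single-arm
        tree = grow_tree(X, y, t, X, y, np.ones(len(y)), min_leaf=5)
        assert np.isnan(tree.tau[tree.feature == -1]).all()

    def test_tree_dict_roundtrip(self):
        X, y, t = self._two_level_fixture()
        tree = grow_tree(X, y, t, X, y, t, min_leaf=5)
        back = Tree.from_dict(tree.to_dict())
        np.testing.assert_array_equal(back.feature, tree.feature)
        np.testing.assert_allclose(back.tau, tree.tau)
        np.testing.assert_array_equal(back.apply(X), tree.apply(X))


class TestHonestCausalForest:
    def _heterogeneous_data(self, n=3_000, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
            rng.uniform(-0.5, 0.5, n),
        ])
        t = rng.integers(0, 2, n).astype(float)
        p = 0.1 + 0.4 * X[:, 0] * t
        y = (rng.random(n) < p).astype(float)
        return X, y, t

    def test_recovers_single_factor_effect_gap(self):
        X, y, t = self._heterogeneous_data()
        forest = HonestCausalForest(
            n_trees=200, min_leaf=25, random_state=0
        ).fit(X, y, t)
        tau = forest.predict(X)
        gap = tau[X[:, 0] == 1].mean() - tau[X[:, 0] == 0].mean()
        assert gap == pytest.approx(0.4, abs=0.08)
        assert tau[X[:, 0] == 0].mean() == pytest.approx(0.0, abs=0.06)

    def test_constant_effect_predicts_constant(self):
        rng = np.random.default_rng(2)
        n = 400
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        t = np.tile([1.0, 0.0], n // 2)
        y = t.copy()          # every leaf tau is exactly 1
        forest = HonestCausalForest(
            n_trees=20, min_leaf=5, random_state=0
        ).fit(X, y, t)
        np.testing.assert_allclose(forest.predict(X), 1.0)

    def test_single_tree_equals_grow_tree_on_its_subsample(self):
        X, y, t = self._heterogeneous_data(n=500, seed=3)
        forest = HonestCausalForest(
            n_trees=1, min_leaf=10, random_state=7
        ).fit(X, y, t)
        sub = forest.subsample_indices_[0]
        sp, est = sub[:forest.split_n_], sub[forest.split_n_:]
        # regrow with the same rows; structure and leaf effects agree
        tree = grow_tree(X[sp], y[sp], t[sp], X[est], y[est], t[est],
                         min_leaf=10)
        got = forest.trees_[0]
        np.testing.assert_array_equal(got.feature, tree.feature)
        np.testing.assert_allclose(got.threshold, tree.threshold)
        np.testing.assert_allclose(got.tau, tree.tau)

    def test_seeded_determinism(self):
        X, y, t = self._heterogeneous_data(n=800, seed=4)
        a = HonestCausalForest(n_trees=30, min_leaf=10,
                               random_state=11).fit(X, y, t)
        b = HonestCausalForest(n_trees=30, min_leaf=10,
                               random_state=11).fit(X, y, t)
        np.testing.assert_array_equal(a.predict_oob(), b.predict_oob())
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_oob_requires_out_of_sample_trees(self):
        X, y, t = self._heterogeneous_data(n=200, seed=5)
        forest = HonestCausalForest(
            n_trees=5, min_leaf=5, subsample_fraction=1.0, random_state=0
        ).fit(X, y, t)
        # every tree contains every patient: no OOB estimate exists
        assert np.isnan(forest.predict_oob()).all()
        assert np.isfinite(forest.predict(X)).all()

    def test_input_validation(self):
        X, y, t = self._heterogeneous_data(n=100, seed=6)
        with pytest.raises(EstimationError):
            HonestCausalForest(n_trees=2).fit(X, y, np.ones(100))
        with pytest.raises(ValueError):
            HonestCausalForest(n_trees=2).fit(X, y, t * 0.5)
        forest = HonestCausalForest(n_trees=2, min_leaf=5,
                                    random_state=0).fit(X, y, t)
        with pytest.raises(ValueError):
            forest.predict(X[:, :2])

    def test_sklearn_param_interface(self):
        forest = HonestCausalForest(n_trees=7)
        assert forest.get_params()["n_trees"] == 7
        forest.set_params(min_leaf=3)
        assert forest.min_leaf == 3
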