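import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helixhand as hh
from helixhand.id3 import NO_GAIN, TreeNode, _GAIN_EPS
from helixhand.torsion import ANGLE_NAMES


def exact_entropy(counts):
    """High-precision direct evaluation of -sum p_i log2 p_i."""
    from fractions import Fraction
    total = sum(counts)
    value = 0.0
    for c in counts:
        if c:
            p = Fraction(c, total)
            value -= float(p) * math.log2(float(p))
    return value


def brute_best_split(X, y, features=ANGLE_NAMES):
    """Exhaustive search over all midpoints on all candidate features."""
    n = len(y)
    parent = hh.entropy((np.sum(y == 0), np.sum(y == 1)))
    best = None
    for feat in features:
        j = ANGLE_NAMES.index(feat)
        values = sorted(set(X[:, j]))
        for lo, hi in zip(values, values[1:]):
            theta = (lo + hi) / 2
            left = y[X[:, j] <= theta]
            right = y[X[:, j] > theta]
            child = (
                len(left) * hh.entropy((np.sum(left == 0), np.sum(left == 1)))
                + len(right) * hh.entropy((np.sum(right == 0), np.sum(right == 1)))
            ) / n
            gain = parent - child
            if gain <= _GAIN_EPS:
                continue
            if best is None or gain > best[2]:
                best = (feat, theta, gain)
    return best


def pad7(columns):
    """Embed a few feature columns into a full 7-column matrix (rest zero)."""
    X = np.zeros((len(columns[0]), 7))
    for j, col in enumerate(columns):
        X[:, j] = col
    return X


class TestEntropy:
    def test_pure_set_is_zero(self):
        assert hh.entropy((4, 0)) == 0.0

    def test_even_split_is_one(self):
        assert hh.entropy((2, 2)) == 1.0

    def test_three_one_matches_direct_formula(self):
        assert hh.entropy((3, 1)) == pytest.approx(exact_entropy((3, 1)), abs=1e-12)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        if a + b == 0:
            with pytest.raises(ValueError):
                hh.entropy((a, b))
            return
        e = hh.entropy((a, b))
        assert 0.0 <= e <= 1.0
        assert e == pytest.approx(hh.entropy((b, a)))

    @given(st.integers(1, 200), st.integers(1, 200))
    @settings(derandomize=True)
    def test_maximal_at_even_proportions(self, a, b):
        assert hh.entropy((a, b)) <= hh.entropy((a + b, a + b)) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hh.entropy((0, 0))


class TestBestSplit:
    def test_perfectly_separable_midpoint(self):
        X = pad7([[170, 175, 300, 310]])
        y = np.array([0, 0, 1, 1])
        feat, theta, gain = hh.best_split(X, y, ["alpha"])
        assert feat == "alpha"
        assert theta == pytest.approx(237.5)
        assert gain == pytest.approx(1.0)

    def test_single_label_no_gain(self):
        X = pad7([[1.0, 2.0, 3.0]])
        assert hh.best_split(X, np.zeros(3, int)) is NO_GAIN

    def test_constant_features_no_gain(self):
        X = np.full((6, 7), 42.0)
        y = np.array([0, 1, 0, 1, 0, 1])
        assert hh.best_split(X, y) is NO_GAIN

    def test_matches_brute_force_enumeration(self, spec):
        """Vectorized search equals exhaustive midpoint enumeration on
        random class-separable draws."""
        for seed in range(10):
            ds = hh.sample_dataset(spec.with_counts(LHG4=50, RHG4=50), seed=seed,
                                   classes=["LHG4", "RHG4"])
            X, y = ds.feature_matrix(), ds.labels
            feat, theta, gain = hh.best_split(X, y)
            bfeat, btheta, bgain = brute_best_split(X, y)
            assert (feat, theta) == (bfeat, btheta)
            assert gain == pytest.approx(bgain, abs=1e-12)

    def test_tie_breaks_by_feature_order(self):
        # identical separating power on alpha and beta -> alpha chosen
        col = [10.0, 20.0, 30.0, 40.0]
        X = pad7([col, col])
        y = np.array([0, 0, 1, 1])
        feat, theta, _ = hh.best_split(X, y)
        assert feat == "alpha" and theta == pytest.approx(25.0)


class TestGrowTree:
    def test_pure_dataset_single_leaf(self):
        X = pad7([[1.0, 2.0, 3.0]])
        tree = hh.grow_tree(X, np.zeros(3, int))
        assert tree.is_leaf and tree.class_counts == (3, 0)

    def test_four_sample_stump(self):
        X = pad7([[170, 175, 300, 310]])
        y = np.array([0, 0, 1, 1])
        tree = hh.grow_tree(X, y)
        assert not tree.is_leaf
        assert tree.feature == "alpha" and tree.threshold == pytest.approx(237.5)
        assert tree.left.is_leaf and tree.left.class_counts == (2, 0)
        assert tree.right.is_leaf and tree.right.class_counts == (0, 2)

    @staticmethod
    def optimal_correct(X, y, depth):
        """Brute-force maximum training hits of any threshold tree of the
        given depth over the first two feature columns (memoized)."""
        import functools

        @functools.lru_cache(maxsize=None)
        def rec(idx, d):
            idx_arr = np.array(idx)
            yi = y[idx_arr]
            majority = max(int((yi == 0).sum()), int((yi == 1).sum()))
            if d == 0 or majority == len(idx):
                return majority
            best = majority
            for j in range(2):
                values = sorted(set(X[idx_arr, j]))
                for lo, hi in zip(values, values[1:]):
                    mask = X[idx_arr, j] <= (lo + hi) / 2
                    best = max(best, rec(tuple(idx_arr[mask]), d - 1)
                               + rec(tuple(idx_arr[~mask]), d - 1))
            return best

        return rec(tuple(range(len(y))), depth)

    def test_matches_depth_limited_optimum_on_class_structured_data(self, spec):
        """On small draws from the class-conditional generator (alpha/beta
        features only), the greedy tree's training accuracy equals the
        brute-force optimal threshold tree of the same depth."""
        for seed in range(12):
            ds = hh.sample_dataset(spec.with_counts(LHG4=6, RHG4=6), seed=seed,
                                   classes=["LHG4", "RHG4"])
            X = pad7([ds.feature_matrix()[:, 0], ds.feature_matrix()[:, 1]])
            y = ds.labels
            tree = hh.grow_tree(X, y, candidate_features=["alpha", "beta"])
            acc = hh.accuracy(tree, X, y)
            opt = self.optimal_correct(X, y, tree.depth()) / len(y)
            assert acc == pytest.approx(opt)

    def test_never_beats_depth_limited_optimum(self):
        """Greedy training accuracy is bounded by the brute-force optimum
        of the same depth, even on adversarial label patterns."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            X = pad7([rng.integers(0, 4, n).astype(float),
                      rng.integers(0, 4, n).astype(float)])
            y = rng.integers(0, 2, n)
            tree = hh.grow_tree(X, y)
            acc = hh.accuracy(tree, X, y)
            opt = self.optimal_correct(X, y, tree.depth()) / n
            assert acc <= opt + 1e-12

    def test_no_conflicts_means_perfect_training_fit(self, spec):
        ds = hh.g4_dataset(spec, seed=21)
        tree = hh.grow_tree(ds)
        assert hh.accuracy(tree, ds) == 1.0

    def test_deterministic(self, g4):
        t1 = hh.grow_tree(g4)
        t2 = hh.grow_tree(g4)
        assert hh.describe(t1) == hh.describe(t2)

    def test_min_gain_stopping_alternative(self, g4):
        shallow = hh.grow_tree(g4, min_gain=0.5)
        full = hh.grow_tree(g4)
        assert shallow.depth() <= full.depth()


class TestPrune:
    def test_zero_alpha_is_identity(self, g4):
        tree = hh.grow_tree(g4)
        assert hh.describe(hh.prune(tree, 0.0)) == hh.describe(tree)

    def test_infinite_alpha_single_leaf(self, g4):
        pruned = hh.prune(hh.grow_tree(g4), math.inf)
        assert pruned.is_leaf
        assert pruned.class_counts == g4.class_counts()

    def test_idempotent(self, g4):
        tree = hh.grow_tree(g4)
        once = hh.prune(tree, 0.04)
        twice = hh.prune(once, 0.04)
        assert hh.describe(once) == hh.describe(twice)

    def test_does_not_mutate_input(self, g4):
        tree = hh.grow_tree(g4)
        before = hh.describe(tree)
        hh.prune(tree, math.inf)
        assert hh.describe(tree) == before

    def test_information_gain_nonnegative_at_every_kept_split(self, g4):
        tree = hh.prune(hh.grow_tree(g4), 0.04)

        def check(node):
            if node.is_leaf:
                return
            parent = hh.entropy(node.class_counts)
            n = node.n_samples
            child = (node.left.n_samples * hh.entropy(node.left.class_counts)
                     + node.right.n_samples * hh.entropy(node.right.class_counts)) / n
            assert parent - child > 0
            check(node.left)
            check(node.right)

        check(tree)

    def test_agrees_with_reference_library(self, spec):
        """Pruned-tree holdout accuracy within 3 points of scikit-learn's
        entropy tree at the same complexity parameter, over 50 draws."""
        from sklearn.tree import DecisionTreeClassifier

        for seed in range(50):
            ds = hh.g4_dataset(spec, seed=300 + seed)
            train, test = hh.holdout_split(ds, seed=seed)
            ours = hh.prune(hh.grow_tree(train), 0.04)
            acc = hh.accuracy(ours, test)
            clf = DecisionTreeClassifier(
                criterion="entropy", ccp_alpha=0.04, random_state=0)
            clf.fit(train.feature_matrix(), train.labels)
            ref = clf.score(test.feature_matrix(), test.labels)
            assert abs(acc - ref) <= 0.03


class TestPredict:
    def test_single_leaf_majority(self):
        leaf = TreeNode(class_counts=(5, 1))
        assert hh.predict(leaf, np.zeros(7)) == 0

    def test_leaf_tie_predicts_left_handed(self):
        leaf = TreeNode(class_counts=(3, 3))
        assert hh.predict(leaf, np.zeros(7)) == 0

    def test_hand_built_alpha_rule_tree(self):
        tree = TreeNode(
            class_counts=(10, 10), feature="alpha", threshold=252.0,
            left=TreeNode(class_counts=(10, 0)),
            right=TreeNode(class_counts=(0, 10)),
        )
        sample = dict(zip(ANGLE_NAMES, [180.0] * 7))
        assert hh.predict(tree, sample) == 0
        sample["alpha"] = 300.0
        assert hh.predict(tree, sample) == 1

    def test_boundary_routing_is_strict(self):
        tree = TreeNode(
            class_counts=(1, 1), feature="beta", threshold=150.0,
            left=TreeNode(class_counts=(1, 0)),
            right=TreeNode(class_counts=(0, 1)),
        )
        at = dict(zip(ANGLE_NAMES, [0, 150.0, 0, 0, 0, 0, 0]))
        above = dict(zip(ANGLE_NAMES, [0, 150.0 + 1e-9, 0, 0, 0, 0, 0]))
        assert hh.predict(tree, at) == 0        # <= goes left
        assert hh.predict(tree, above) == 1

    def test_missing_feature_is_an_error(self):
        tree = TreeNode(class_counts=(1, 1), feature="alpha", threshold=100.0,
                        left=TreeNode(class_counts=(1, 0)),
                        right=TreeNode(class_counts=(0, 1)))
        with pytest.raises(ValueError):
            hh.predict(tree, {"beta": 100.0})

    def test_predict_many_matches_predict(self, g4):
        tree = hh.prune(hh.grow_tree(g4), 0.04)
        X = g4.feature_matrix()
        singles = np.array([hh.predict(tree, x) for x in X])
        np.testing.assert_array_equal(hh.predict_many(tree, X), singles)


class TestRuleClassifier:
    @pytest.mark.parametrize("alpha,beta,expected", [
        (180.0, 200.0, 0),   # low alpha, high beta -> left-handed
        (300.0, 200.0, 1),   # high alpha -> right-handed
        (180.0, 100.0, 1),   # low beta -> right-handed
        (252.0, 200.0, 1),   # boundary: alpha must be strictly below 252
        (180.0, 150.0, 1),   # boundary: beta must be strictly above 150
    ])
    def test_rule(self, alpha, beta, expected):
        sample = dict(zip(ANGLE_NAMES, [alpha, beta, 0, 0, 0, 0, 0]))
        assert hh.rule_classifier(sample) == expected

    def test_missing_angles_rejected(self):
        with pytest.raises(ValueError):
            hh.rule_classifier({"alpha": 180.0})


class TestSerialization:
    def test_describe_parse_fixed_point(self, g4):
        tree = hh.prune(hh.grow_tree(g4), 0.04)
        text = hh.describe(tree)
        assert hh.describe(hh.parse_description(text)) == text

    def test_single_leaf_renders_counts(self):
        assert hh.describe(TreeNode(class_counts=(5, 1))) == "leaf counts=5,1\n"

    def test_two_level_tree_renders_both_thresholds(self):
        tree = TreeNode(
            class_counts=(3, 2), feature="alpha", threshold=252.0,
            left=TreeNode(class_counts=(3, 1), feature="beta", threshold=150.0,
                          left=TreeNode(class_counts=(0, 1)),
                          right=TreeNode(class_counts=(3, 0))),
            right=TreeNode(class_counts=(0, 1)),
        )
        text = hh.describe(tree)
        assert "feature=alpha theta=252.0" in text
        assert "feature=beta theta=150.0" in text
        assert hh.describe(hh.parse_description(text)) == text

    def test_json_round_trip(self, g4):
        tree = hh.prune(hh.grow_tree(g4), 0.04)
        back = hh.tree_from_json(hh.tree_to_json(tree))
        assert hh.describe(back) == hh.describe(tree)
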