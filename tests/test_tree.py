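"""From-scratch decision tree: Gini, split search, fitting, splitting, importance."""
import numpy as np
import pytest

from shakesense.tree import (
    DecisionTree,
    InternalNode,
    Leaf,
    best_split,
    feature_importance,
    fit_tree,
    gini,
    predict,
    split_data,
)


def brute_force_best_split(X, y):
    """Independent oracle: enumerate every (feature, midpoint) candidate.

    Gini decreases are computed in exact rational arithmetic so that ties are
    broken by the stated deterministic rule (lower feature index, then
    smaller threshold) rather than by floating-point noise.
    """
    from fractions import Fraction

    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, f = X.shape

    def g(labels):
        m = len(labels)
        if m == 0:
            return Fraction(0)
        c1 = int(labels.sum())
        return 1 - Fraction(c1, m) ** 2 - Fraction(m - c1, m) ** 2

    parent = g(y)
    best = None
    for j in range(f):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            mask = X[:, j] <= thr
            dec = parent - (
                int(mask.sum()) * g(y[mask]) + int((~mask).sum()) * g(y[~mask])
            ) / n
            if dec > 0 and (best is None or dec > best[2]):
                best = (j, thr, dec)
    if best is None:
        return None
    return (best[0], best[1], float(best[2]))


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((2, 1), 4.0 / 9.0), ((0, 7), 0.0)],
    )
    def test_known_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))

    def test_binary_bound(self, rng):
        for _ in range(50):
            c = rng.integers(0, 100, size=2)
            if c.sum() == 0:
                continue
            assert 0.0 <= gini(c) <= 0.5


class TestBestSplit:
    def test_hand_enumerated_example(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        sp = best_split(X, y)
        assert sp.feature_index == 0
        assert sp.threshold == 5.0
        assert sp.impurity_decrease == pytest.approx(0.5)

    def test_pure_labels_give_none(self):
        X = np.array([[1.0], [2.0], [3.0]])
        assert best_split(X, np.zeros(3, int)) is None

    def test_constant_feature_gives_none(self):
        X = np.ones((6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        assert best_split(X, y) is None

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(5, 21)
        X = rng.uniform(size=(n, 3))
        y = rng.integers(0, 2, size=n)
        expected = brute_force_best_split(X, y)
        got = best_split(X, y)
        if expected is None:
            assert got is None
        else:
            assert (got.feature_index, got.threshold) == expected[:2]
            assert got.impurity_decrease == pytest.approx(expected[2], abs=1e-12)

    def test_matches_brute_force_with_tied_values(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            X = rng.integers(0, 4, size=(n, 3)).astype(float)  # many ties
            y = rng.integers(0, 2, size=n)
            expected = brute_force_best_split(X, y)
            got = best_split(X, y)
            if expected is None:
                assert got is None
            else:
                assert (got.feature_index, got.threshold) == expected[:2]


class TestFitPredict:
    def test_pure_input_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        tree = fit_tree(X, np.ones(10, int))
        assert isinstance(tree.root, Leaf)
        assert predict(tree, X).tolist() == [1] * 10

    def test_depth_cap_respected(self, rng):
        # XOR-ish data needs depth > 2 for purity
        X = rng.uniform(size=(200, 4))
        y = ((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5) ^ (X[:, 2] > 0.5)).astype(int)
        tree = fit_tree(X, y, max_depth=2)
        assert tree.depth() <= 2

    def test_training_accuracy_beats_majority_baseline(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 4))
            y = (X[:, 0] + 0.5 * r.normal(size=60) > 0).astype(int)
            tree = fit_tree(X, y)
            acc = (predict(tree, X) == y).mean()
            baseline = max(y.mean(), 1 - y.mean())
            assert acc >= baseline

    def test_hand_traced_routing(self):
        root = InternalNode(
            feature_index=1, threshold=0.5, impurity_decrease=0.5, counts=(2, 2),
            left=Leaf(counts=(2, 0), prediction=0),
            right=Leaf(counts=(0, 2), prediction=1),
        )
        tree = DecisionTree(root=root, max_depth=2, n_features=2)
        X = np.array([[9.0, 0.4], [9.0, 0.5], [0.0, 0.51], [0.0, 2.0]])
        assert predict(tree, X).tolist() == [0, 0, 1, 1]

    def test_fitting_is_deterministic(self, rng):
        X = rng.normal(size=(100, 5))
        y = rng.integers(0, 2, size=100)
        t1 = fit_tree(X, y)
        t2 = fit_tree(X, y)
        assert t1.to_dict() == t2.to_dict()

    def test_parent_counts_equal_sum_of_children(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        tree = fit_tree(X, y, max_depth=2)

        def check(node):
            if isinstance(node, Leaf):
                return node.counts
            lc = check(node.left)
            rc = check(node.right)
            assert node.counts == (lc[0] + rc[0], lc[1] + rc[1])
            return node.counts

        check(tree.root)

    def test_leaf_tie_predicts_aggressive(self):
        X = np.ones((4, 1))
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y)
        assert isinstance(tree.root, Leaf) and tree.root.prediction == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_tree(np.empty((0, 3)), np.empty(0, int))

    def test_dimension_mismatch_on_predict(self, rng):
        tree = fit_tree(rng.normal(size=(10, 3)), rng.integers(0, 2, 10))
        with pytest.raises(ValueError):
            predict(tree, rng.normal(size=(5, 2)))

    def test_agrees_with_sklearn_on_random_data(self):
        """Independent cross-check: same root split and training accuracy as
        sklearn's CART on continuous random data."""
        from sklearn.tree import DecisionTreeClassifier

        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 4))
            y = (X[:, 1] - 0.7 * X[:, 2] + 0.3 * rng.normal(size=80) > 0).astype(int)
            ours = fit_tree(X, y, max_depth=2)
            ref = DecisionTreeClassifier(
                criterion="gini", max_depth=2, random_state=0
            ).fit(X, y)
            assert ours.root.feature_index == ref.tree_.feature[0]
            assert ours.root.threshold == pytest.approx(ref.tree_.threshold[0], abs=1e-7)
            acc_ours = (predict(ours, X) == y).mean()
            acc_ref = ref.score(X, y)
            assert acc_ours == pytest.approx(acc_ref, abs=1e-12)


class TestSplitData:
    def test_sizes(self):
        y = np.r_[np.zeros(600, int), np.ones(400, int)]
        tr, te = split_data(y, train_frac=0.7, seed=0)
        assert len(tr) == 700 and len(te) == 300

    def test_stratification_preserves_proportions(self):
        y = np.r_[np.zeros(600, int), np.ones(400, int)]
        tr, _ = split_data(y, train_frac=0.7, seed=1)
        assert abs(int(np.sum(y[tr] == 1)) - 280) <= 1
        assert abs(int(np.sum(y[tr] == 0)) - 420) <= 1

    def test_same_seed_identical_partition(self):
        y = np.random.default_rng(0).integers(0, 2, 500)
        a = split_data(y, seed=42)
        b = split_data(y, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_partition_is_disjoint_and_complete(self):
        y = np.random.default_rng(1).integers(0, 2, 301)
        tr, te = split_data(y, seed=5)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == 301

    def test_group_split_keeps_groups_together(self):
        y = np.random.default_rng(2).integers(0, 2, 300)
        groups = np.repeat(np.arange(10), 30)
        tr, te = split_data(y, seed=3, group_ids=groups)
        assert set(groups[tr]).isdisjoint(set(groups[te]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.zeros(10, int), train_frac=1.0)


class TestFeatureImportance:
    def test_single_split_concentrates_importance(self):
        X = np.array([[1.0, 9.9], [2.0, 9.9], [8.0, 9.9], [9.0, 9.9]])
        y = np.array([0, 0, 1, 1])
        imp, normalized = feature_importance(fit_tree(X, y))
        assert normalized
        np.testing.assert_allclose(imp, [1.0, 0.0])

    def test_importances_sum_to_one(self, rng):
        X = rng.normal(size=(200, 6))
        y = ((X[:, 0] > 0) & (X[:, 3] > 0.2)).astype(int)
        imp, normalized = feature_importance(fit_tree(X, y, max_depth=2))
        assert normalized
        assert imp.sum() == pytest.approx(1.0)
        assert np.all(imp >= 0)

    def test_single_leaf_flagged_unnormalized(self):
        imp, normalized = feature_importance(fit_tree(np.ones((5, 3)), np.ones(5, int)))
        assert not normalized
        np.testing.assert_array_equal(imp, np.zeros(3))


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(100, 4))
        y = (X[:, 2] > 0).astype(int)
        tree = fit_tree(X, y, max_depth=2)
        path = tree.save(tmp_path / "model.json")
        back = DecisionTree.load(path)
        assert back.to_dict() == tree.to_dict()
        np.testing.assert_array_equal(predict(back, X), predict(tree, X))
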