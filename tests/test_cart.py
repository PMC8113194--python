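from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from parkdx import cart
from parkdx.cart import (
    DecisionTree,
    PathEntry,
    TreeNode,
    best_split,
    cross_validate,
    feature_importance,
    gini_impurity,
    grow_tree,
    predict,
    predict_frame,
    prune_path,
    select_min_1se,
    tree_from_json,
    tree_to_dict,
    tree_to_json,
)

from conftest import random_instance
from oracles import brute_best_split, brute_grow, dp_optimal_subtree, tree_signature


def two_blob_frame(n=40, gap_lo=1.0, gap_hi=2.0, seed=0):
    """Two classes perfectly separable on x with a data gap (gap_lo, gap_hi)."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.uniform(0, gap_lo, n // 2), rng.uniform(gap_hi, 3, n // 2)])
    return pd.DataFrame({"x": x, "group": ["A"] * (n // 2) + ["B"] * (n // 2)})


class TestGini:
    def test_pure_node(self):
        assert gini_impurity([10, 0, 0, 0, 0]) == 0.0

    def test_two_balanced_classes(self):
        assert gini_impurity([5, 5]) == 0.5

    def test_reference_cohort_class_counts(self):
        # 1 - (80^2+90^2+21^2+16^2+9^2)/216^2 = 15689/23328
        assert gini_impurity([80, 90, 21, 16, 9]) == pytest.approx(
            float(Fraction(15689, 23328)), abs=1e-12
        )

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])


class TestBestSplit:
    def test_perfect_separation(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        j, thr, dec = best_split(X, y, ["x"], 2, minbucket=1)
        assert j == 0
        assert thr == pytest.approx(5.5)
        assert dec == pytest.approx(0.5)  # full parent impurity removed

    def test_constant_features_no_split(self):
        X = np.ones((8, 2))
        y = np.array([0, 1] * 4)
        assert best_split(X, y, ["a", "b"], 2, minbucket=1) is None

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            df, feats = random_instance(rng)
            classes = sorted(set(df["group"]))
            cidx = {c: i for i, c in enumerate(classes)}
            X = df[feats].to_numpy(float)
            y = np.array([cidx[v] for v in df["group"]])
            mine = best_split(X, y, feats, len(classes), minbucket=2)
            oracle = brute_best_split(X, y, len(classes), minbucket=2)
            if oracle is None:
                assert mine is None
            else:
                assert mine is not None
                assert (mine[0], mine[1]) == (oracle[0], pytest.approx(oracle[1]))
                checked += 1
        assert checked >= 20  # most random instances admit a split


class TestGrow:
    def test_single_class_is_leaf(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "group": ["A"] * 3})
        tree = grow_tree(df, ["x"], minsplit=2, minbucket=1)
        assert tree.root.is_leaf
        assert tree.root.predicted_class == "A"

    def test_separable_two_class_depth_one(self):
        df = two_blob_frame()
        tree = grow_tree(df, ["x"], minsplit=5, minbucket=2)
        assert tree.depth() == 1
        assert (predict_frame(tree, df) == df["group"]).all()

    def test_class_count_conservation(self, cohort216):
        tree = grow_tree(cohort216)
        for node in cart._walk(tree.root):
            if not node.is_leaf:
                assert np.array_equal(
                    node.counts, node.left.counts + node.right.counts
                )
        leaf_total = sum(
            n.n for n in cart._walk(tree.root) if n.is_leaf
        )
        assert leaf_total == len(cohort216)

    def test_matches_bruteforce_grow(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            df, feats = random_instance(rng, n_max=50)
            classes = tuple(sorted(set(df["group"])))
            tree = grow_tree(df, feats, minsplit=8, minbucket=3, max_depth=4)
            sig = brute_grow(df, tuple(feats), classes,
                             minsplit=8, minbucket=3, max_depth=4)
            # thresholds are midpoints computed identically -> exact equality
            assert tree_signature(tree.root) == sig

    def test_matches_sklearn_on_tie_free_data(self):
        """Independent cross-check: on continuous data (no tied values or
        tied scores), growth agrees with sklearn's CART split for split."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 120
            df = pd.DataFrame(
                {
                    "a": rng.normal(size=n),
                    "b": rng.normal(size=n),
                    "c": rng.normal(size=n),
                }
            )
            df["group"] = np.where(
                df["a"] + 0.5 * rng.normal(size=n) > 0, "pos", "neg"
            )
            mine = grow_tree(df, ["a", "b", "c"], minsplit=20, minbucket=7,
                             max_depth=3)
            ref = sklearn_tree.DecisionTreeClassifier(
                criterion="gini", min_samples_split=20, min_samples_leaf=7,
                max_depth=3, random_state=0,
            ).fit(df[["a", "b", "c"]], df["group"])
            assert mine.root.feature == ["a", "b", "c"][ref.tree_.feature[0]]
            # sklearn casts features to float32; thresholds agree only to that
            assert mine.root.threshold == pytest.approx(
                ref.tree_.threshold[0], abs=1e-5
            )
            mine_pred = predict_frame(mine, df).to_numpy()
            ref_pred = ref.predict(df[["a", "b", "c"]])
            assert (mine_pred == ref_pred).mean() > 0.98

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(pd.DataFrame({"x": [], "group": []}), ["x"])


class TestPrunePath:
    def test_stump_input_gives_length_one(self):
        df = pd.DataFrame({"x": [1.0] * 10, "group": ["A"] * 5 + ["B"] * 5})
        tree = grow_tree(df, ["x"], minsplit=2, minbucket=1)
        path = prune_path(tree)
        assert len(path) == 1
        assert path[0].tree.root.is_leaf

    def test_path_invariants(self, cohort216):
        tree = grow_tree(cohort216, minsplit=5, minbucket=2)
        path = prune_path(tree)
        alphas = [e.alpha for e in path]
        leaves = [e.n_leaves for e in path]
        rel = [e.rel_error for e in path]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))
        assert all(a > b for a, b in zip(leaves, leaves[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(rel, rel[1:]))  # error grows
        assert path[-1].tree.root.is_leaf
        assert path[-1].rel_error == pytest.approx(1.0)

    def test_path_matches_dp_enumeration(self):
        """Every path subtree is the cost-complexity-optimal subtree (by
        exhaustive bottom-up DP) at its own alpha and mid-interval."""
        rng = np.random.default_rng(7)
        for _ in range(15):
            df, feats = random_instance(rng, n_max=60)
            tree = grow_tree(df, feats, minsplit=5, minbucket=2, max_depth=5)
            path = prune_path(tree)
            r_root = max(
                int(tree.root.counts.sum() - tree.root.counts.max()), 1
            )
            for k, entry in enumerate(path):
                test_alphas = [entry.alpha_raw]
                if k + 1 < len(path):
                    test_alphas.append(
                        (entry.alpha_raw + path[k + 1].alpha_raw) / 2
                    )
                for alpha in test_alphas:
                    _, sig = dp_optimal_subtree(tree.root, Fraction(alpha))
                    assert sig == tree_signature(entry.tree.root)
                assert entry.rel_error == pytest.approx(
                    sum(
                        int(n.counts.sum() - n.counts.max())
                        for n in cart._walk(entry.tree.root)
                        if n.is_leaf
                    )
                    / r_root
                )


class TestCrossValidate:
    def test_deterministic_given_seed(self, cohort216):
        a = cross_validate(cohort216, seed=3)
        b = cross_validate(cohort216, seed=3)
        assert [e.xerror for e in a] == [e.xerror for e in b]
        assert [e.xstd for e in a] == [e.xstd for e in b]

    def test_separable_data_reaches_zero_xerror(self):
        df = two_blob_frame(n=60)
        path = cross_validate(df, ["x"], minsplit=5, minbucket=2, folds=5, seed=0)
        assert min(e.xerror for e in path) == pytest.approx(0.0)

    def test_permuted_labels_have_no_structure(self, cohort216):
        """With labels randomly permuted no subtree should cross-validate
        materially better than the root stump."""
        rng = np.random.default_rng(12)
        below = 0
        reps = 10
        for _ in range(reps):
            df = cohort216.copy()
            df["group"] = rng.permutation(df["group"].to_numpy())
            path = cross_validate(df, folds=5, seed=int(rng.integers(2**31)))
            xmin = min(e.xerror for e in path)
            xstd = max(e.xstd for e in path)
            if xmin < 1.0 - 2 * xstd:
                below += 1
        assert below <= 2  # allow rare fluctuations

    def test_fold_validation(self, cohort216):
        with pytest.raises(ValueError):
            cross_validate(cohort216, folds=1)
        with pytest.raises(ValueError):
            cross_validate(cohort216.head(5), folds=10)


def _dummy_path(xerrors, xstds):
    """PathEntry list over shrinking, individually tagged dummy trees.

    Path order is increasing alpha, i.e. decreasing tree size; each tree's
    leaf class encodes its position so the selected subtree is identifiable
    after cloning.
    """
    entries = []
    for i, (xe, xs) in enumerate(zip(xerrors, xstds)):
        leaf = TreeNode(predicted_class=f"T{i}", counts=np.array([5, 3]))
        tree = DecisionTree(root=leaf, classes=("A", "B"), features=("x",))
        entries.append(
            PathEntry(alpha=float(i), tree=tree, n_leaves=len(xerrors) - i,
                      rel_error=0.5, xerror=xe, xstd=xs)
        )
    return entries


class TestMin1SE:
    def test_profile_with_shoulder(self):
        # (full -> stump) profile 0.36, 0.35, 0.4, 1.0: min 0.35 has SE 0.05
        # -> cutoff 0.40; smallest subtree at or under it has xerror 0.4
        path = _dummy_path([0.36, 0.35, 0.4, 1.0], [0.05, 0.05, 0.05, 0.1])
        assert select_min_1se(path).root.predicted_class == "T2"

    def test_flat_profile_selects_stump(self):
        path = _dummy_path([0.5, 0.5, 0.5], [0.05, 0.05, 0.05])
        assert select_min_1se(path).root.predicted_class == "T2"

    def test_improving_full_tree_is_kept(self):
        # xerror worsens as the tree shrinks and the SE is tiny: nothing
        # but the full tree qualifies
        path = _dummy_path([0.3, 0.6, 1.0], [1e-6, 1e-6, 1e-6])
        assert select_min_1se(path).root.predicted_class == "T0"

    def test_requires_cv_errors(self):
        path = _dummy_path([0.5], [0.1])
        path[0].xerror = None
        with pytest.raises(ValueError):
            select_min_1se(path)


class TestImportance:
    def test_depth_one_tree_concentrates_importance(self):
        df = two_blob_frame()
        df["noise"] = np.linspace(0, 1, len(df))
        tree = grow_tree(df, ["x", "noise"], minsplit=5, minbucket=2)
        imp = feature_importance(tree)
        assert imp["x"] == pytest.approx(1.0)
        assert imp["noise"] == 0.0

    def test_importances_sum_to_one(self, cohort216):
        tree = grow_tree(cohort216)
        imp = feature_importance(tree)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        unused = set(tree.features) - set(tree.features_used())
        assert all(imp[f] == 0.0 for f in unused)

    def test_stump_is_degenerate(self):
        df = pd.DataFrame({"x": [1.0] * 10, "group": ["A"] * 6 + ["B"] * 4})
        tree = grow_tree(df, ["x"], minsplit=2, minbucket=1)
        with pytest.warns(UserWarning, match="degenerate"):
            imp = feature_importance(tree)
        assert (imp == 0.0).all()


class TestPredict:
    def test_boundary_value_routes_left(self):
        df = two_blob_frame()
        tree = grow_tree(df, ["x"], minsplit=5, minbucket=2)
        thr = tree.root.threshold
        assert predict(tree, {"x": thr}) == tree.root.left.predicted_class

    def test_missing_feature_raises(self):
        df = two_blob_frame()
        tree = grow_tree(df, ["x"], minsplit=5, minbucket=2)
        with pytest.raises(ValueError, match="missing feature"):
            predict(tree, {"y": 1.0})

    def test_resubstitution_on_pure_tree(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.permutation(20).astype(float)})
        df["group"] = np.where(df["x"] % 2 == 0, "even", "odd")
        tree = grow_tree(df, ["x"], minsplit=2, minbucket=1, max_depth=30)
        assert (predict_frame(tree, df) == df["group"]).all()


class TestSerialization:
    def test_json_round_trip(self, cohort216):
        tree = grow_tree(cohort216)
        back = tree_from_json(tree_to_json(tree))
        assert tree_signature(back.root) == tree_signature(tree.root)
        assert tree_to_dict(back) == tree_to_dict(tree)

    def test_render_and_dot(self, cohort216):
        tree = grow_tree(cohort216)
        text = cart.render_text(tree)
        dot = cart.to_dot(tree)
        n_nodes = sum(1 for _ in cart._walk(tree.root))
        node_defs = [l for l in dot.splitlines() if "label=" in l and "->" not in l]
        assert len(node_defs) == n_nodes
        assert dot.count("->") == 2 * tree.n_internal()
        assert text.count("leaf ->") == tree.n_leaves()

    def test_malformed_json_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            tree_from_json("{\"classes\": []}")
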