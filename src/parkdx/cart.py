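"""From-scratch CART engine: Gini-impurity growth, weakest-link
cost-complexity pruning, stratified cross-validation, Min-1SE model
selection and Gini feature importance.

The engine is written for exact reproducibility rather than raw speed:

* Candidate split thresholds are midpoints between consecutive distinct
  sorted values; routing convention is "``<=`` goes left".
* Split scores and weakest-link ``g`` values are compared with exact
  integer/rational arithmetic, so ties never depend on floating-point
  summation order.  Ties break deterministically: first by the fixed
  feature order of the training columns, then by the smallest threshold,
  and predicted classes break count ties by the fixed class order.
* Pruning-path errors are misclassification counts scaled relative to the
  root stump (the ``rel error`` / ``xerror`` convention of recursive
  partitioning software); the complexity parameter ``alpha`` is likewise
  reported relative to the root error.
"""

from __future__ import annotations

import copy
import json
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .cohort import FEATURES, GROUPS

__all__ = [
    "TreeNode",
    "DecisionTree",
    "PathEntry",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "prune_path",
    "cross_validate",
    "select_min_1se",
    "feature_importance",
    "predict",
    "predict_frame",
    "tree_to_dict",
    "tree_from_dict",
    "tree_to_json",
    "tree_from_json",
    "render_text",
    "to_dot",
]


# ---------------------------------------------------------------------------
# Data structures

@dataclass
class TreeNode:
    """One node of a binary classification tree.

    ``counts`` is the per-class training count vector (fixed class order);
    it may be ``None`` for externally specified trees (e.g. a published
    tree whose per-leaf tallies are unknown).
    """

    predicted_class: str
    counts: np.ndarray | None = None
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.counts.sum()) if self.counts is not None else 0


@dataclass
class DecisionTree:
    """A grown or fixed classification tree over named numeric features."""

    root: TreeNode
    classes: tuple[str, ...]
    features: tuple[str, ...]

    def n_leaves(self) -> int:
        return sum(1 for node in _walk(self.root) if node.is_leaf)

    def n_internal(self) -> int:
        return sum(1 for node in _walk(self.root) if not node.is_leaf)

    def depth(self) -> int:
        def d(node):
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def features_used(self) -> tuple[str, ...]:
        used = {node.feature for node in _walk(self.root) if not node.is_leaf}
        return tuple(f for f in self.features if f in used)


@dataclass
class PathEntry:
    """One step of the cost-complexity pruning path.

    ``alpha`` is the complexity parameter scaled relative to the root-stump
    misclassification count (the CP convention); ``rel_error`` the
    resubstitution error on the same scale; ``xerror``/``xstd`` are filled
    by :func:`cross_validate`.
    """

    alpha: float
    tree: DecisionTree
    n_leaves: int
    rel_error: float
    alpha_raw: Fraction = field(default_factory=lambda: Fraction(0), repr=False)
    xerror: float | None = None
    xstd: float | None = None


def _walk(node: TreeNode):
    yield node
    if not node.is_leaf:
        yield from _walk(node.left)
        yield from _walk(node.right)


# ---------------------------------------------------------------------------
# Impurity and split search

def gini_impurity(counts) -> float:
    """Gini impurity ``1 - sum_c p_c**2`` of a class-count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty node has no impurity")
    p = counts / n
    return float(1.0 - (p * p).sum())


def _class_order(labels) -> tuple[str, ...]:
    """Deterministic class order: the canonical diagnostic order when the
    labels are diagnostic groups, lexicographic otherwise."""
    uniq = set(labels)
    if uniq <= set(GROUPS):
        return tuple(g for g in GROUPS if g in uniq)
    return tuple(sorted(uniq))


def _scan_feature(x: np.ndarray, y: np.ndarray, n_classes: int, minbucket: int):
    """Best split of one feature.

    Returns ``(S, D, threshold)`` where ``S/D`` is the integer-exact score
    ``sum_c cL_c^2 / nL + sum_c cR_c^2 / nR`` to be maximized, or ``None``
    when no admissible split exists.  Ties prefer the smallest threshold.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), ys] = 1
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    nl = np.arange(1, n, dtype=np.int64)  # left size for a cut after index i
    nr = n - nl
    valid = (xs[:-1] != xs[1:]) & (nl >= minbucket) & (nr >= minbucket)
    if not valid.any():
        return None

    left_sq = (cum[:-1] ** 2).sum(axis=1)
    right_sq = ((total - cum[:-1]) ** 2).sum(axis=1)
    S = left_sq * nr + right_sq * nl  # score numerator, denominator D = nl*nr
    D = nl * nr
    score = np.where(valid, S / D, -np.inf)
    best = float(score.max())
    # resolve near-ties exactly with integer cross-multiplication
    cand = np.flatnonzero(valid & (score >= best - 1e-9 * max(1.0, abs(best))))
    bi = int(cand[0])
    for i in cand[1:]:
        i = int(i)
        if int(S[i]) * int(D[bi]) > int(S[bi]) * int(D[i]):
            bi = i
    threshold = 0.5 * (float(xs[bi]) + float(xs[bi + 1]))
    return int(S[bi]), int(D[bi]), threshold


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    n_classes: int,
    minbucket: int = 1,
):
    """Exhaustive best Gini split over all features and midpoints.

    Returns ``(feature_index, threshold, impurity_decrease)`` or ``None``
    when no split strictly decreases the weighted impurity.  Tie-breaks:
    feature order of ``feature_names``, then smallest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    counts = np.bincount(y, minlength=n_classes).astype(np.int64)
    parent_sq = int((counts**2).sum())

    best = None  # (S, D, feature_index, threshold)
    for j in range(X.shape[1]):
        res = _scan_feature(X[:, j], y, n_classes, minbucket)
        if res is None:
            continue
        S, D, thr = res
        if best is None or S * best[1] > best[0] * D:
            best = (S, D, j, thr)
    if best is None:
        return None
    S, D, j, thr = best
    # positive decrease requires S/D > parent_sq / n
    if S * n <= parent_sq * D:
        return None
    decrease = (S / D - parent_sq / n) / n  # weighted Gini decrease
    return j, thr, float(decrease)


# ---------------------------------------------------------------------------
# Growth

def grow_tree(
    data: pd.DataFrame,
    features=FEATURES,
    label: str = "group",
    minsplit: int = 20,
    minbucket: int = 7,
    max_depth: int = 30,
) -> DecisionTree:
    """Grow a classification tree by recursive binary Gini partitioning.

    Stopping rules: a node is not split when it is pure, has fewer than
    ``minsplit`` rows, sits at ``max_depth``, or no split leaves at least
    ``minbucket`` rows per child while strictly decreasing impurity.
    """
    if len(data) == 0:
        raise ValueError("cannot grow a tree on an empty table")
    features = tuple(features)
    classes = _class_order(data[label])
    class_idx = {c: i for i, c in enumerate(classes)}
    X = data[list(features)].to_numpy(dtype=float)
    y = np.array([class_idx[v] for v in data[label]], dtype=np.int64)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=len(classes)).astype(np.int64)
        node = TreeNode(
            predicted_class=classes[int(np.argmax(counts))], counts=counts
        )
        n = len(idx)
        if n < minsplit or depth >= max_depth or counts.max() == n:
            return node
        found = best_split(X[idx], y[idx], features, len(classes), minbucket)
        if found is None:
            return node
        j, thr, _ = found
        mask = X[idx, j] <= thr
        node.feature = features[j]
        node.threshold = thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return DecisionTree(root=root, classes=classes, features=features)


# ---------------------------------------------------------------------------
# Cost-complexity pruning

def _node_risk(node: TreeNode) -> int:
    """Misclassification count if the node were a leaf."""
    return int(node.counts.sum() - node.counts.max())


def _subtree_risk(node: TreeNode) -> int:
    if node.is_leaf:
        return _node_risk(node)
    return _subtree_risk(node.left) + _subtree_risk(node.right)


def _subtree_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _subtree_leaves(node.left) + _subtree_leaves(node.right)


def _collapse(node: TreeNode) -> None:
    node.feature = None
    node.threshold = None
    node.left = None
    node.right = None


def _collapse_where_g_equals(node: TreeNode, g_target: Fraction) -> None:
    """Collapse every internal node whose weakest-link g equals ``g_target``,
    topmost first (descendants of a collapsed node vanish with it)."""
    if node.is_leaf:
        return
    g = Fraction(_node_risk(node) - _subtree_risk(node), _subtree_leaves(node) - 1)
    if g == g_target:
        _collapse(node)
        return
    _collapse_where_g_equals(node.left, g_target)
    _collapse_where_g_equals(node.right, g_target)


def _min_g(node: TreeNode) -> Fraction | None:
    if node.is_leaf:
        return None
    g = Fraction(_node_risk(node) - _subtree_risk(node), _subtree_leaves(node) - 1)
    for child_g in (_min_g(node.left), _min_g(node.right)):
        if child_g is not None and child_g < g:
            g = child_g
    return g


def prune_path(tree: DecisionTree) -> list[PathEntry]:
    """Weakest-link cost-complexity pruning path.

    Produces the nested subtree sequence ``T_1 > T_2 > ... > stump`` with
    strictly increasing complexity parameters; each step collapses every
    internal node minimizing the per-leaf error increase
    ``g = (R(node) - R(subtree)) / (leaves - 1)``.  All internal nodes with
    ``g = 0`` are collapsed before the first entry, so ``T_1`` is the
    smallest subtree with the full tree's resubstitution error.
    """
    work = copy.deepcopy(tree)
    r_root = _node_risk(work.root) if work.root.counts is not None else 0
    scale = r_root if r_root > 0 else 1  # pure root: degenerate, avoid 0/0

    entries: list[PathEntry] = []
    alpha = Fraction(0)
    # collapse free structure (g == 0) at alpha = 0
    while not work.root.is_leaf:
        g = _min_g(work.root)
        if g != 0:
            break
        _collapse_where_g_equals(work.root, g)
    while True:
        entries.append(
            PathEntry(
                alpha=float(alpha) / scale,
                alpha_raw=alpha,
                tree=copy.deepcopy(work),
                n_leaves=_subtree_leaves(work.root),
                rel_error=_subtree_risk(work.root) / scale,
            )
        )
        if work.root.is_leaf:
            break
        g = _min_g(work.root)
        if g <= alpha:
            raise AssertionError("pruning alphas must be strictly increasing")
        alpha = g
        # collapsing can lower an ancestor's g; keep pruning until the
        # weakest remaining link is strictly above the current alpha
        while not work.root.is_leaf:
            m = _min_g(work.root)
            if m is None or m > alpha:
                break
            _collapse_where_g_equals(work.root, m)
    return entries


# ---------------------------------------------------------------------------
# Cross-validation and Min-1SE selection

def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Per-class round-robin fold assignment after a seeded shuffle.
    Classes with fewer members than folds are spread as evenly as possible."""
    assign = np.empty(len(y), dtype=np.int64)
    offset = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assign[idx] = (np.arange(len(idx)) + offset) % folds
        offset += len(idx)  # stagger so small classes do not pile on fold 0
    return assign


def _best_subtree_at(path: list[PathEntry], beta: float) -> DecisionTree:
    """The path subtree optimal for complexity penalty ``beta`` (the entry
    with the largest alpha not exceeding ``beta``)."""
    alphas = [e.alpha for e in path]
    i = bisect_right(alphas, beta) - 1
    return path[max(i, 0)].tree


def cross_validate(
    data: pd.DataFrame,
    features=FEATURES,
    label: str = "group",
    minsplit: int = 20,
    minbucket: int = 7,
    max_depth: int = 30,
    folds: int = 10,
    seed: int = 0,
) -> list[PathEntry]:
    """Grow, prune and fill the pruning path with cross-validated errors.

    Stratified ``folds``-fold CV: for every main-path step the fold trees
    are pruned at the geometric mean of the step's alpha interval, the held
    out fold is predicted, and the pooled misclassification count is scaled
    by the root-stump error (``xerror``), with a binomial-style standard
    error on the same scale (``xstd``).
    """
    n = len(data)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError("more folds than rows")
    features = tuple(features)
    full = grow_tree(data, features, label, minsplit, minbucket, max_depth)
    path = prune_path(full)
    r_root = max(_node_risk(full.root), 1)

    # geometric-mean representative alpha for each path interval
    alphas = [e.alpha for e in path]
    betas = [
        float(np.sqrt(alphas[k] * alphas[k + 1])) if k + 1 < len(alphas) else np.inf
        for k in range(len(alphas))
    ]

    rng = np.random.default_rng(seed)
    classes = full.classes
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[v] for v in data[label]], dtype=np.int64)
    assign = _stratified_folds(y, folds, rng)

    miss = np.zeros(len(path), dtype=np.int64)
    for f in range(folds):
        train = data.loc[np.asarray(assign != f)]
        test = data.loc[np.asarray(assign == f)]
        if len(test) == 0:
            continue
        fold_tree = grow_tree(train, features, label, minsplit, minbucket, max_depth)
        fold_path = prune_path(fold_tree)
        truth = test[label].to_numpy()
        for k, beta in enumerate(betas):
            sub = _best_subtree_at(fold_path, beta)
            pred = predict_frame(sub, test)
            miss[k] += int((pred.to_numpy() != truth).sum())

    for k, entry in enumerate(path):
        m = int(miss[k])
        entry.xerror = m / r_root
        entry.xstd = float(np.sqrt(m * (n - m) / n)) / r_root
    return path


def select_min_1se(path: list[PathEntry]) -> DecisionTree:
    """Smallest subtree whose ``xerror`` is within one SE of the minimum.

    The SE used is the one attached to the minimizing entry; among
    qualifying subtrees the one with the largest alpha (fewest leaves) is
    returned.
    """
    if any(e.xerror is None for e in path):
        raise ValueError("path has no cross-validated errors; run cross_validate")
    imin = int(np.argmin([e.xerror for e in path]))
    # tiny guard so an xerror exactly at min + 1 SE qualifies despite
    # floating-point representation of the sum
    cutoff = path[imin].xerror + path[imin].xstd + 1e-12
    chosen = max(
        (e for e in path if e.xerror <= cutoff), key=lambda e: e.alpha
    )
    return copy.deepcopy(chosen.tree)


# ---------------------------------------------------------------------------
# Importance and prediction

def feature_importance(tree: DecisionTree) -> pd.Series:
    """Gini importance: per-feature sum of weighted impurity decreases over
    the nodes splitting on that feature, normalized to sum to one."""
    total = {f: 0.0 for f in tree.features}
    n_root = tree.root.n
    if n_root == 0:
        raise ValueError("tree carries no training counts")
    for node in _walk(tree.root):
        if node.is_leaf:
            continue
        n, nl, nr = node.n, node.left.n, node.right.n
        dec = gini_impurity(node.counts) - (
            nl / n * gini_impurity(node.left.counts)
            + nr / n * gini_impurity(node.right.counts)
        )
        total[node.feature] += n / n_root * dec
    s = sum(total.values())
    if s <= 0:
        warnings.warn("stump tree: feature importance is degenerate (all zero)")
        return pd.Series(total, dtype=float)
    return pd.Series({f: v / s for f, v in total.items()}, dtype=float)


def predict(tree: DecisionTree, x) -> str:
    """Classify one observation (mapping or Series of feature values).

    Routing convention: ``value <= threshold`` goes left.
    """
    node = tree.root
    while not node.is_leaf:
        try:
            v = x[node.feature]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"missing feature {node.feature!r}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing feature {node.feature!r}")
        node = node.left if v <= node.threshold else node.right
    return node.predicted_class


def predict_frame(tree: DecisionTree, data: pd.DataFrame) -> pd.Series:
    """Vectorized prediction over the rows of a cohort table."""
    used = tree.features_used()
    missing = [f for f in used if f not in data.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    n = len(data)
    out = np.empty(n, dtype=object)
    idx = np.arange(n)
    cols = {f: data[f].to_numpy(dtype=float) for f in used}

    def route(node: TreeNode, rows: np.ndarray) -> None:
        if len(rows) == 0:
            return
        if node.is_leaf:
            out[rows] = node.predicted_class
            return
        mask = cols[node.feature][rows] <= node.threshold
        route(node.left, rows[mask])
        route(node.right, rows[~mask])

    route(tree.root, idx)
    return pd.Series(out, index=data.index, name="predicted")


# ---------------------------------------------------------------------------
# Serialization and rendering

def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {"class": node.predicted_class}
    if node.counts is not None:
        d["counts"] = [int(c) for c in node.counts]
    if not node.is_leaf:
        d["feature"] = node.feature
        d["threshold"] = node.threshold
        d["children"] = [_node_to_dict(node.left), _node_to_dict(node.right)]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    counts = np.asarray(d["counts"], dtype=np.int64) if "counts" in d else None
    node = TreeNode(predicted_class=d["class"], counts=counts)
    if "children" in d:
        node.feature = d["feature"]
        node.threshold = float(d["threshold"])
        node.left = _node_from_dict(d["children"][0])
        node.right = _node_from_dict(d["children"][1])
    return node


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "classes": list(tree.classes),
        "features": list(tree.features),
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> DecisionTree:
    return DecisionTree(
        root=_node_from_dict(d["root"]),
        classes=tuple(d["classes"]),
        features=tuple(d["features"]),
    )


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=2)


def tree_from_json(text: str) -> DecisionTree:
    try:
        return tree_from_dict(json.loads(text))
    except (KeyError, IndexError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed tree JSON: {exc}") from exc


def render_text(tree: DecisionTree) -> str:
    """Indented text rendering of splits, thresholds, counts and leaf classes."""
    lines: list[str] = []

    def emit(node: TreeNode, indent: int, prefix: str) -> None:
        pad = "  " * indent
        counts = ""
        if node.counts is not None:
            counts = " counts=" + "/".join(str(int(c)) for c in node.counts)
        if node.is_leaf:
            lines.append(f"{pad}{prefix}leaf -> {node.predicted_class}{counts}")
        else:
            lines.append(
                f"{pad}{prefix}{node.feature} <= {node.threshold:g}?{counts}"
            )
            emit(node.left, indent + 1, "yes: ")
            emit(node.right, indent + 1, "no:  ")

    emit(tree.root, 0, "")
    return "\n".join(lines)


def to_dot(tree: DecisionTree) -> str:
    """GraphViz DOT rendering (one box per node)."""
    lines = ["digraph tree {", "  node [shape=box];"]
    counter = {"i": 0}

    def emit(node: TreeNode) -> int:
        nid = counter["i"]
        counter["i"] += 1
        if node.is_leaf:
            lines.append(f'  n{nid} [label="{node.predicted_class}"];')
        else:
            lines.append(f'  n{nid} [label="{node.feature} <= {node.threshold:g}"];')
            lid, rid = emit(node.left), emit(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
        return nid

    emit(tree.root)
    lines.append("}")
    return "\n".join(lines)
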