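"""Independent brute-force oracles for the CART engine.

These deliberately re-derive splits, trees and pruning sequences from the
definitions with naive enumeration and exact rational arithmetic; they share
no code path with ``parkdx.cart``.
"""

from fractions import Fraction

import numpy as np
import pandas as pd


def brute_best_split(X, y, n_classes, minbucket):
    """Exhaustive (feature, threshold) search maximizing the Gini decrease.

    Ties prefer the earlier feature, then the smaller threshold.  Returns
    ``(feature_index, threshold)`` or ``None`` when no admissible split
    strictly decreases impurity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    parent = np.bincount(y, minlength=n_classes)
    parent_score = Fraction(int((parent.astype(object) ** 2).sum()), n)
    best = None
    best_score = None
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (float(a) + float(b))
            mask = X[:, j] <= thr
            nl = int(mask.sum())
            nr = n - nl
            if nl < minbucket or nr < minbucket:
                continue
            cl = np.bincount(y[mask], minlength=n_classes).astype(object)
            cr = np.bincount(y[~mask], minlength=n_classes).astype(object)
            score = Fraction(int((cl**2).sum()), nl) + Fraction(int((cr**2).sum()), nr)
            if best_score is None or score > best_score:
                best_score = score
                best = (j, thr)
    if best is None or best_score <= parent_score:
        return None
    return best


def brute_grow(df: pd.DataFrame, features, classes, label="group",
               minsplit=20, minbucket=7, max_depth=30):
    """Recursive brute-force tree growth; returns a nested signature
    ``("leaf", class)`` / ``(feature, threshold, left, right)``."""
    class_idx = {c: i for i, c in enumerate(classes)}
    X = df[list(features)].to_numpy(dtype=float)
    y = np.array([class_idx[v] for v in df[label]], dtype=np.int64)

    def build(idx, depth):
        counts = np.bincount(y[idx], minlength=len(classes))
        pred = classes[int(np.argmax(counts))]
        n = len(idx)
        if n < minsplit or depth >= max_depth or counts.max() == n:
            return ("leaf", pred)
        found = brute_best_split(X[idx], y[idx], len(classes), minbucket)
        if found is None:
            return ("leaf", pred)
        j, thr = found
        mask = X[idx, j] <= thr
        return (
            features[j],
            thr,
            build(idx[mask], depth + 1),
            build(idx[~mask], depth + 1),
        )

    return build(np.arange(len(y)), 0)


def tree_signature(node):
    """Signature of a ``parkdx.cart.TreeNode`` in the oracle's format."""
    if node.is_leaf:
        return ("leaf", node.predicted_class)
    return (
        node.feature,
        node.threshold,
        tree_signature(node.left),
        tree_signature(node.right),
    )


def dp_optimal_subtree(node, alpha: Fraction):
    """Cost-complexity-optimal pruning of ``node`` at penalty ``alpha`` by
    bottom-up dynamic programming (ties collapse, yielding the smallest
    optimal subtree).  Returns ``(total_cost, signature)``."""
    risk = Fraction(int(node.counts.sum() - node.counts.max()))
    collapsed = (risk + alpha, ("leaf", node.predicted_class))
    if node.is_leaf:
        return collapsed
    cl, sl = dp_optimal_subtree(node.left, alpha)
    cr, sr = dp_optimal_subtree(node.right, alpha)
    kept = (cl + cr, (node.feature, node.threshold, sl, sr))
    return collapsed if collapsed[0] <= kept[0] else kept
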