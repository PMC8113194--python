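"""Model/Results surface tying the pipeline together.

:class:`DiagnosticTreeModel` is built from a cohort table (six quantitative
indices plus a diagnosis label); ``fit()`` grows a CART, cross-validates its
cost-complexity pruning path, applies the Min-1SE rule and returns a
:class:`TreeResults` carrying the selected tree, the pruning-path table,
Gini feature importances and per-class diagnostic metrics.

:class:`PublishedTreeClassifier` exposes the fixed published tree through
the same Results-style interface (predict / evaluate / summary), for
deploying the published cutoffs on new data without refitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cart, dxtree, evaluate
from .cohort import FEATURES, FEATURE_LABELS, GROUPS, default_group_models, generate_cohort

__all__ = ["DiagnosticTreeModel", "TreeResults", "PublishedTreeClassifier"]


class DiagnosticTreeModel:
    """CART diagnostic model over a labelled cohort of quantitative indices."""

    def __init__(self, data: pd.DataFrame, features=FEATURES, label: str = "group"):
        features = tuple(features)
        missing = [c for c in (*features, label) if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if len(data) == 0:
            raise ValueError("cohort table is empty")
        if data[list(features)].isna().any().any():
            raise ValueError("cohort table contains missing index values")
        self.data = data.reset_index(drop=True)
        self.features = features
        self.label = label

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "DiagnosticTreeModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosticTreeModel":
        from .cohort import read_cohort

        return cls(read_cohort(path), **kwargs)

    @classmethod
    def simulate(
        cls, seed: int = 0, sizes: dict[str, int] | None = None, models=None, **kwargs
    ) -> "DiagnosticTreeModel":
        """Build a model on a seeded synthetic cohort (published group
        statistics by default)."""
        cohort = generate_cohort(
            models or default_group_models(), sizes=sizes, seed=seed
        )
        return cls(cohort, **kwargs)

    def fit(
        self,
        minsplit: int = 20,
        minbucket: int = 7,
        max_depth: int = 30,
        folds: int = 10,
        seed: int = 0,
        prune: str = "min1se",
    ) -> "TreeResults":
        """Grow, cross-validate and prune; return a :class:`TreeResults`.

        ``prune`` is ``"min1se"`` (smallest subtree within one SE of the
        minimum cross-validated error), ``"min"`` (subtree at the minimum
        xerror) or ``"none"`` (the fully grown tree).
        """
        path = cart.cross_validate(
            self.data,
            self.features,
            self.label,
            minsplit=minsplit,
            minbucket=minbucket,
            max_depth=max_depth,
            folds=folds,
            seed=seed,
        )
        if prune == "min1se":
            tree = cart.select_min_1se(path)
        elif prune == "min":
            best = min(path, key=lambda e: (e.xerror, -e.alpha))
            tree = best.tree
        elif prune == "none":
            tree = path[0].tree
        else:
            raise ValueError("prune must be 'min1se', 'min' or 'none'")
        return TreeResults(self, tree, path, params={
            "minsplit": minsplit,
            "minbucket": minbucket,
            "max_depth": max_depth,
            "folds": folds,
            "seed": seed,
            "prune": prune,
        })


class TreeResults:
    """Fitted-tree results: estimates, uncertainty (cross-validated error
    profile) and diagnostics."""

    def __init__(self, model, tree, path, params):
        self.model = model
        self.tree = tree
        self.path = path
        self.params = params

    # -- estimates ---------------------------------------------------------
    @property
    def cp_table(self) -> pd.DataFrame:
        """Pruning-path table: alpha, n_leaves, rel_error, xerror, xstd."""
        return pd.DataFrame(
            {
                "alpha": [e.alpha for e in self.path],
                "n_leaves": [e.n_leaves for e in self.path],
                "rel_error": [e.rel_error for e in self.path],
                "xerror": [e.xerror for e in self.path],
                "xstd": [e.xstd for e in self.path],
            }
        )

    @property
    def importances(self) -> pd.Series:
        """Gini feature importances of the selected tree (sum to 1)."""
        if self.tree.root.is_leaf:
            return pd.Series({f: 0.0 for f in self.tree.features})
        return cart.feature_importance(self.tree)

    @property
    def cutoffs(self) -> pd.DataFrame:
        """All (feature, threshold) splits of the selected tree."""
        rows = [
            {"feature": node.feature, "threshold": node.threshold}
            for node in cart._walk(self.tree.root)
            if not node.is_leaf
        ]
        return pd.DataFrame(rows, columns=["feature", "threshold"])

    # -- prediction and evaluation ----------------------------------------
    def predict(self, data: pd.DataFrame | None = None) -> pd.Series:
        if data is None:
            data = self.model.data
        return cart.predict_frame(self.tree, data)

    def evaluate(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """One-vs-rest metrics of the selected tree on ``data`` (training
        data when omitted, i.e. resubstitution performance)."""
        if data is None:
            data = self.model.data
        pred = self.predict(data)
        return evaluate.metrics_table(data[self.model.label], pred, GROUPS)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = ["Diagnostic decision tree (CART, Gini, Min-1SE pruning)"]
        lines.append("=" * len(lines[0]))
        n = len(self.model.data)
        lines.append(f"n = {n} patients, {len(self.model.features)} indices, "
                     f"{self.tree.n_leaves()} leaves after pruning")
        lines.append(f"growth: minsplit={self.params['minsplit']} "
                     f"minbucket={self.params['minbucket']} "
                     f"max_depth={self.params['max_depth']}; "
                     f"{self.params['folds']}-fold CV, seed={self.params['seed']}, "
                     f"selection={self.params['prune']}")
        lines.append("")
        lines.append("Pruning path (errors relative to the root stump):")
        lines.append(self.cp_table.to_string(index=False, float_format="%.4f"))
        lines.append("")
        lines.append("Feature importance (Gini):")
        imp = self.importances.sort_values(ascending=False)
        for f, v in imp.items():
            lines.append(f"  {FEATURE_LABELS.get(f, f):<12} {v:.3f}")
        lines.append("")
        lines.append("Selected tree:")
        lines.append(cart.render_text(self.tree))
        return "\n".join(lines)

    def to_json(self) -> str:
        return cart.tree_to_json(self.tree)

    def plot_importances(self, ax=None):
        """Horizontal bar chart of the Gini feature importances."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        imp = self.importances.sort_values()
        ax.barh(
            [FEATURE_LABELS.get(f, f) for f in imp.index], imp.to_numpy()
        )
        ax.set_xlabel("Gini importance")
        return ax

    def plot_index_distributions(self, ax=None, index: str = "sbr"):
        """Per-group box plot of one quantitative index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        data = self.model.data
        groups = [g for g in GROUPS if g in set(data[self.model.label])]
        ax.boxplot(
            [data.loc[data[self.model.label] == g, index] for g in groups],
            tick_labels=groups,
        )
        ax.set_ylabel(FEATURE_LABELS.get(index, index))
        return ax


class PublishedTreeClassifier:
    """The published fixed tree behind a Results-style interface."""

    def __init__(self, tree=None):
        self.tree = tree if tree is not None else dxtree.default_published_tree()

    def predict(self, data: pd.DataFrame) -> pd.Series:
        return dxtree.classify_cohort(data, self.tree)

    def predict_one(self, x) -> str:
        return dxtree.classify_patient(x, self.tree)

    def evaluate(self, data: pd.DataFrame, label: str = "group") -> pd.DataFrame:
        pred = self.predict(data)
        return evaluate.metrics_table(data[label], pred, GROUPS)

    def summary(self) -> str:
        lines = ["Published diagnostic decision tree"]
        lines.append("=" * len(lines[0]))
        lines.append(
            "cutoffs: "
            + ", ".join(
                f"{FEATURE_LABELS[f]} {t:g}" for f, t in dxtree.CUTOFFS.items()
            )
        )
        lines.append("output classes: NPS, PD, DLB, PSP (MSA is never emitted)")
        lines.append("")
        lines.append(cart.render_text(self.tree))
        return "\n".join(lines)
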