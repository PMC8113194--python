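"""The published optimal decision tree as a fixed, deployable classifier.

Four cutoffs over four of the six indices separate the diagnostic groups::

    PCR <= 0.81?
    ├── yes: H/M (Delay) <= 2.26?
    │        ├── yes: PD
    │        └── no:  SBR <= 0.91?
    │                 ├── yes: PSP
    │                 └── no:  PD   (residual leaf, see below)
    └── no:  WR <= 44.55?
             ├── yes: NPS
             └── no:  DLB

AI and H/M (Early) are never consulted and MSA is never predicted (the
source analysis could not separate MSA).  The residual leaf (preserved
putamen-to-caudate shape is absent, cardiac innervation preserved, but SBR
still normal-ish) defaults to PD, the by-far largest Parkinsonian group;
because the published figure does not pin this leaf down unambiguously, the
whole topology can be overridden from a tree-JSON file.

Cutoff comparisons use the published two-decimal values verbatim with the
"``<=`` goes left" routing convention.
"""

from __future__ import annotations

import pandas as pd

from .cart import DecisionTree, TreeNode, predict, predict_frame, tree_from_json

__all__ = [
    "CUTOFFS",
    "REQUIRED_FEATURES",
    "default_published_tree",
    "classify_patient",
    "classify_cohort",
    "load_tree_file",
]

#: Published split thresholds of the optimal tree.
CUTOFFS = {"pcr": 0.81, "wr": 44.55, "hm_delay": 2.26, "sbr": 0.91}

#: Indices a patient record must provide to be classified.
REQUIRED_FEATURES = ("pcr", "wr", "hm_delay", "sbr")


def default_published_tree() -> DecisionTree:
    """Build the default reconstruction of the published tree."""
    leaf = lambda cls: TreeNode(predicted_class=cls)  # noqa: E731
    sbr_node = TreeNode(
        predicted_class="PD",
        feature="sbr",
        threshold=CUTOFFS["sbr"],
        left=leaf("PSP"),
        right=leaf("PD"),
    )
    hm_node = TreeNode(
        predicted_class="PD",
        feature="hm_delay",
        threshold=CUTOFFS["hm_delay"],
        left=leaf("PD"),
        right=sbr_node,
    )
    wr_node = TreeNode(
        predicted_class="NPS",
        feature="wr",
        threshold=CUTOFFS["wr"],
        left=leaf("NPS"),
        right=leaf("DLB"),
    )
    root = TreeNode(
        predicted_class="NPS",
        feature="pcr",
        threshold=CUTOFFS["pcr"],
        left=hm_node,
        right=wr_node,
    )
    return DecisionTree(
        root=root,
        classes=("NPS", "PD", "DLB", "PSP", "MSA"),
        features=("hm_early", "hm_delay", "wr", "sbr", "pcr", "ai"),
    )


def load_tree_file(path) -> DecisionTree:
    """Load an alternative tree topology from a tree-JSON file."""
    from pathlib import Path

    return tree_from_json(Path(path).read_text())


def classify_patient(x, tree: DecisionTree | None = None) -> str:
    """Classify one patient record (mapping/Series of index values).

    Requires PCR, WR, H/M (Delay) and SBR; AI and H/M (Early) are ignored.
    """
    if tree is None:
        tree = default_published_tree()
    for feat in REQUIRED_FEATURES:
        try:
            v = x[feat]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"missing required index {feat!r}") from exc
        if v is None or pd.isna(v):
            raise ValueError(f"missing required index {feat!r}")
    return predict(tree, x)


def classify_cohort(cohort: pd.DataFrame, tree: DecisionTree | None = None) -> pd.Series:
    """Vectorized classification of a cohort table; returns a ``predicted``
    series aligned with the cohort index."""
    if tree is None:
        tree = default_published_tree()
    return predict_frame(tree, cohort)
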