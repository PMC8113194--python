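"""Diagnostic-performance metrics and nonparametric group-difference tests.

Per-class performance is one-vs-rest: the 5-class truth and the (at most
4-class) tree prediction are dichotomized against each class, giving
TP/FP/FN/TN and the usual percentages::

    sensitivity = 100 * TP / (TP + FN)     specificity = 100 * TN / (TN + FP)
    PPV         = 100 * TP / (TP + FP)     NPV         = 100 * TN / (TN + FN)
    accuracy    = 100 * (TP + TN) / n

MSA is evaluated like any other truth class, but a classifier that can
never emit MSA has TP = 0 by construction; its row is flagged degenerate.

Group differences use the Kruskal-Wallis rank test (tie-corrected H,
chi-squared reference) with Dunn's rank z-tests as the post hoc, adjusted
by Bonferroni over all unordered group pairs; pairwise Mann-Whitney is
available as an alternative post hoc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUPS

__all__ = [
    "ClassMetrics",
    "GroupTestResult",
    "confusion_counts",
    "class_metrics",
    "metrics_table",
    "kruskal_wallis",
    "posthoc_bonferroni",
    "round_half_up",
    "PUBLISHED_TREE_CONFUSION",
]

#: Published one-vs-rest confusion tallies of the optimal tree on the
#: 216-patient reference cohort (TP, FP, FN, TN per class), reconstructed
#: from the printed count ratios (e.g. sensitivity 70/80, PPV 70/75).
PUBLISHED_TREE_CONFUSION: dict[str, tuple[int, int, int, int]] = {
    "NPS": (70, 5, 10, 131),
    "PD": (82, 27, 8, 99),
    "DLB": (12, 8, 9, 187),
    "PSP": (8, 4, 8, 196),
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 93.05 -> 93.1, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest confusion counts and derived percentages for one class.

    Percentages are kept at full precision; ``rounded()`` renders them to
    one decimal (half-up) for display.  A metric with a zero denominator is
    ``nan`` (undefined), never silently zero.
    """

    class_label: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def degenerate(self) -> bool:
        """True when the class can gather no true positives (e.g. a truth
        class the classifier never emits)."""
        return self.tp == 0

    def rounded(self) -> dict[str, float]:
        out = {}
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, m)
            out[m] = round_half_up(v, 1) if np.isfinite(v) else float("nan")
        return out


def confusion_counts(truth, predicted, class_label: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for ``class_label``."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction vectors differ in length")
    known = set(GROUPS)
    bad = (set(truth) | set(predicted)) - known
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    t = truth == class_label
    p = predicted == class_label
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    return tp, fp, fn, tn


def class_metrics(
    tp: int, fp: int, fn: int, tn: int, class_label: str = ""
) -> ClassMetrics:
    """Wrap raw one-vs-rest counts in a :class:`ClassMetrics`."""
    return ClassMetrics(class_label=class_label, tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_table(truth, predicted, classes=GROUPS) -> pd.DataFrame:
    """Per-class metrics table (one row per class, percentages to 1 dp)."""
    rows = []
    for cls in classes:
        cm = ClassMetrics(cls, *confusion_counts(truth, predicted, cls))
        r = cm.rounded()
        rows.append(
            {
                "class": cls,
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                "sensitivity": r["sensitivity"],
                "specificity": r["specificity"],
                "ppv": r["ppv"],
                "npv": r["npv"],
                "accuracy": r["accuracy"],
                "degenerate": cm.degenerate,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    """Omnibus rank test plus Bonferroni-adjusted pairwise comparisons."""

    index_name: str
    statistic: float
    p_value: float
    df: int
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def _groups_of(cohort: pd.DataFrame, index_name: str):
    if index_name not in cohort.columns:
        raise ValueError(f"unknown index {index_name!r}")
    labels = [g for g in GROUPS if g in set(cohort["group"])]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    samples = [cohort.loc[cohort["group"] == g, index_name].to_numpy() for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 1:
            raise ValueError(f"group {g} is empty")
    return labels, samples


def kruskal_wallis(cohort: pd.DataFrame, index_name: str) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H test across the cohort's groups."""
    labels, samples = _groups_of(cohort, index_name)
    if np.ptp(np.concatenate(samples)) == 0:
        # every observation tied: no rank information, no evidence
        return GroupTestResult(
            index_name=index_name, statistic=0.0, p_value=1.0, df=len(labels) - 1
        )
    h, p = stats.kruskal(*samples)
    return GroupTestResult(
        index_name=index_name, statistic=float(h), p_value=float(p), df=len(labels) - 1
    )


def _dunn_pairwise(labels, samples) -> pd.DataFrame:
    """Dunn's rank z-tests with tie correction over all unordered pairs."""
    all_vals = np.concatenate(samples)
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    pos = 0
    for g, s in zip(labels, samples):
        mean_ranks[g] = ranks[pos : pos + len(s)].mean()
        pos += len(s)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    sizes = {g: len(s) for g, s in zip(labels, samples)}

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(
            max(n_total * (n_total + 1) / 12.0 - tie_term, 0.0)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        diff = mean_ranks[a] - mean_ranks[b]
        # se vanishes only when every observation is tied, whence diff = 0
        z = diff / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": float(z), "p_raw": p_raw})
    return pd.DataFrame(rows)


def _mannwhitney_pairwise(labels, samples) -> pd.DataFrame:
    rows = []
    by = dict(zip(labels, samples))
    for a, b in itertools.combinations(labels, 2):
        u, p = stats.mannwhitneyu(by[a], by[b], alternative="two-sided")
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(u), "p_raw": float(p)}
        )
    return pd.DataFrame(rows)


def posthoc_bonferroni(
    cohort: pd.DataFrame, index_name: str, method: str = "dunn"
) -> GroupTestResult:
    """Post hoc pairwise comparisons with Bonferroni adjustment.

    ``method`` is ``"dunn"`` (rank z-tests, the standard Kruskal-Wallis
    follow-up) or ``"mannwhitney"``.  Adjusted p-values are the raw ones
    multiplied by the number of unordered pairs, capped at 1.
    """
    labels, samples = _groups_of(cohort, index_name)
    omnibus = kruskal_wallis(cohort, index_name)
    if method == "dunn":
        pairs = _dunn_pairwise(labels, samples)
    elif method == "mannwhitney":
        pairs = _mannwhitney_pairwise(labels, samples)
    else:
        raise ValueError("method must be 'dunn' or 'mannwhitney'")
    m = len(pairs)
    pairs["p_adj"] = np.minimum(pairs["p_raw"] * m, 1.0)
    omnibus.pairwise = pairs
    return omnibus
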