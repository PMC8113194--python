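"""Synthetic diagnostic cohorts for Parkinsonian-syndrome classification studies.

Five clinical groups are modelled: NPS (non-Parkinsonian presentations such as
essential tremor), PD (Parkinson's disease), DLB (dementia with Lewy bodies),
PSP (progressive supranuclear palsy) and MSA (multiple system atrophy).  Each
patient carries six quantitative nuclear-medicine indices:

====================  =======================================================
column                meaning
====================  =======================================================
``hm_early``          heart-to-mediastinum MIBG uptake ratio, early image
``hm_delay``          heart-to-mediastinum MIBG uptake ratio, delayed image
``wr``                cardiac MIBG washout rate (percent)
``sbr``               striatal binding ratio (smaller of the two sides)
``pcr``               putamen-to-caudate ratio (smaller of the two sides)
``ai``                striatal asymmetry index (fraction)
====================  =======================================================

The per-group marginals are truncated Gaussians parameterised by the published
group means and standard deviations; only marginal moments are published, so
indices are sampled independently by default, with an optional user-supplied
correlation matrix applied through a Gaussian copula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "FEATURES",
    "FEATURE_LABELS",
    "GroupModel",
    "default_group_models",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "truncated_mean",
]

#: Fixed diagnostic label order (used everywhere ties must break deterministically).
GROUPS: tuple[str, ...] = ("NPS", "PD", "DLB", "PSP", "MSA")

#: Fixed feature order (also the split tie-break order in the CART engine).
FEATURES: tuple[str, ...] = ("hm_early", "hm_delay", "wr", "sbr", "pcr", "ai")

#: Human-readable names for reports and plots.
FEATURE_LABELS: dict[str, str] = {
    "hm_early": "H/M (Early)",
    "hm_delay": "H/M (Delay)",
    "wr": "WR",
    "sbr": "SBR",
    "pcr": "PCR",
    "ai": "AI",
}

# Physiologically plausible hard bounds for each index.  All published group
# means sit well inside these; they only prevent nonsense draws in the tails
# (e.g. a negative H/M ratio or a washout rate above 100%).
_BOUNDS: dict[str, tuple[float, float]] = {
    "hm_early": (0.5, 6.0),
    "hm_delay": (0.5, 6.0),
    "wr": (-30.0, 100.0),
    "sbr": (-0.5, 8.0),
    "pcr": (0.05, 2.5),
    "ai": (0.0, 1.5),
}

# Published per-group marginal mean +/- SD of the six indices, and the group
# sizes of the 216-patient reference cohort (80 NPS + 136 PS).
_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "NPS": {
        "hm_early": (2.61, 0.43),
        "hm_delay": (2.72, 0.54),
        "wr": (29.3, 13.5),
        "sbr": (2.13, 0.51),
        "pcr": (0.85, 0.10),
        "ai": (0.03, 0.02),
    },
    "PD": {
        "hm_early": (1.99, 0.44),
        "hm_delay": (1.82, 0.54),
        "wr": (50.1, 16.1),
        "sbr": (1.08, 0.33),
        "pcr": (0.71, 0.07),
        "ai": (0.09, 0.06),
    },
    "DLB": {
        "hm_early": (1.98, 0.58),
        "hm_delay": (1.73, 0.62),
        "wr": (55.1, 16.0),
        "sbr": (1.10, 0.43),
        "pcr": (0.84, 0.11),
        "ai": (0.08, 0.07),
    },
    "PSP": {
        "hm_early": (2.61, 0.40),
        "hm_delay": (2.67, 0.52),
        "wr": (31.0, 13.3),
        "sbr": (1.01, 0.63),
        "pcr": (0.77, 0.08),
        "ai": (0.08, 0.07),
    },
    "MSA": {
        "hm_early": (2.46, 0.44),
        "hm_delay": (2.50, 0.58),
        "wr": (31.1, 16.4),
        "sbr": (1.24, 0.49),
        "pcr": (0.72, 0.08),
        "ai": (0.10, 0.09),
    },
}

_GROUP_SIZES: dict[str, int] = {"NPS": 80, "PD": 90, "DLB": 21, "PSP": 16, "MSA": 9}


@dataclass(frozen=True)
class GroupModel:
    """Marginal model for one diagnostic group.

    Parameters
    ----------
    label : str
        Group label, one of :data:`GROUPS`.
    means, sds : dict
        Per-index marginal mean and standard deviation (``sd >= 0``).
    bounds : dict
        Per-index ``(lower, upper)`` truncation bounds for the Gaussian.
    n_default : int
        Default group size used when no explicit sizes are requested.
    """

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_BOUNDS)
    )
    n_default: int = 1

    def __post_init__(self) -> None:
        if self.label not in GROUPS:
            raise ValueError(f"unknown group label {self.label!r}")
        for feat in FEATURES:
            if feat not in self.means or feat not in self.sds:
                raise ValueError(f"group {self.label}: missing index {feat!r}")
            if self.sds[feat] < 0:
                raise ValueError(f"group {self.label}: negative sd for {feat!r}")
            lo, hi = self.bounds[feat]
            if not lo < hi:
                raise ValueError(f"group {self.label}: empty bounds for {feat!r}")
        if self.n_default <= 0:
            raise ValueError("n_default must be positive")


def default_group_models() -> list[GroupModel]:
    """The five published group models (means/SDs and group sizes)."""
    return [
        GroupModel(
            label=g,
            means={f: _GROUP_STATS[g][f][0] for f in FEATURES},
            sds={f: _GROUP_STATS[g][f][1] for f in FEATURES},
            n_default=_GROUP_SIZES[g],
        )
        for g in GROUPS
    ]


def truncated_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Closed-form mean of a Gaussian truncated to ``[lo, hi]``."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    k = len(FEATURES)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")
    return corr


def _sample_group(
    model: GroupModel,
    n: int,
    rng: np.random.Generator,
    corr: np.ndarray | None,
) -> pd.DataFrame:
    k = len(FEATURES)
    z = rng.standard_normal((n, k))
    if corr is not None:
        # Gaussian copula: correlate the latent normals, keep the marginals.
        eigvals, eigvecs = np.linalg.eigh(corr)
        root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None))) @ eigvecs.T
        z = z @ root.T
    u = stats.norm.cdf(z)
    cols: dict[str, np.ndarray] = {}
    for j, feat in enumerate(FEATURES):
        mu, sd = model.means[feat], model.sds[feat]
        lo, hi = model.bounds[feat]
        if sd == 0:
            cols[feat] = np.full(n, np.clip(mu, lo, hi))
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            x = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sd)
            cols[feat] = np.clip(x, lo, hi)  # guard ppf round-off at u ~ 0 or 1
    return pd.DataFrame(cols)


def generate_cohort(
    models: list[GroupModel] | None = None,
    sizes: dict[str, int] | None = None,
    seed: int = 0,
    correlation: np.ndarray | dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw a seeded synthetic cohort.

    Parameters
    ----------
    models : list of GroupModel, optional
        Defaults to :func:`default_group_models`.
    sizes : dict, optional
        Per-group sample sizes; defaults to each model's ``n_default``.
    seed : int
        Seed for the pseudo-random generator; identical ``(models, sizes,
        seed, correlation)`` yield an identical table.
    correlation : array or dict of arrays, optional
        A 6x6 correlation matrix (or one per group) applied to the latent
        Gaussians of the copula.  Must be symmetric PSD with unit diagonal.

    Returns
    -------
    pandas.DataFrame
        Columns ``patient_id, group, hm_early, hm_delay, wr, sbr, pcr, ai``.
    """
    if models is None:
        models = default_group_models()
    by_label = {m.label: m for m in models}
    if sizes is None:
        sizes = {m.label: m.n_default for m in models}
    unknown = set(sizes) - set(by_label)
    if unknown:
        raise ValueError(f"sizes given for unknown groups: {sorted(unknown)}")
    for g, n in sizes.items():
        if n <= 0:
            raise ValueError(f"group {g}: size must be positive, got {n}")

    corr_by_group: dict[str, np.ndarray | None]
    if correlation is None:
        corr_by_group = {g: None for g in sizes}
    elif isinstance(correlation, dict):
        corr_by_group = {g: _check_correlation(c) for g, c in correlation.items()}
        for g in sizes:
            corr_by_group.setdefault(g, None)
    else:
        shared = _check_correlation(correlation)
        corr_by_group = {g: shared for g in sizes}

    rng = np.random.default_rng(seed)
    frames = []
    for g in GROUPS:  # fixed group order so the layout is reproducible
        if g not in sizes:
            continue
        n = sizes[g]
        block = _sample_group(by_label[g], n, rng, corr_by_group[g])
        block.insert(0, "group", g)
        block.insert(0, "patient_id", [f"{g}-{i + 1:04d}" for i in range(n)])
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


_COLUMNS = ["patient_id", "group"] + list(FEATURES)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the canonical column order."""
    cohort.loc[:, _COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (canonical schema, known labels, no NaN)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"cohort CSV contains unknown group labels: {sorted(bad)}")
    if df[list(FEATURES)].isna().any().any():
        raise ValueError("cohort CSV contains missing index values")
    return df[_COLUMNS]
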