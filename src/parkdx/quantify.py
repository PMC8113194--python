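"""Quantitative index computation for DAT SPECT and cardiac MIBG scintigraphy.

DAT SPECT indices (from striatal/occipital VOI mean counts):

* **SBR** (striatal binding ratio): background-subtracted striatal mean over
  the occipital reference mean, ``(S - O) / O``.  Note some vendor tools
  report the un-subtracted ratio ``S / O``; this package always subtracts.
* **PCR** (putamen-to-caudate ratio): putamen VOI mean over caudate VOI mean.
* **AI** (asymmetry index): absolute left-right SBR difference divided by the
  mean of both sides (a fraction, not a percent).

For SBR and PCR the smaller of the two sides is the reported value.  The
per-side SBR uses the voxel-weighted union mean of the caudate and putamen
VOIs (a whole-striatum value; the sub-regions are not reported separately).

MIBG indices (from heart/mediastinum ROI count densities on paired planar
images acquired early, ~15 min, and delayed, ~3 h, post-injection):

* **H/M**: heart ROI count density over mediastinum ROI count density, one
  value per image.
* **WR** (washout rate, percent)::

      WR = 100 * [(He - Me) - (Hd - Md)/k] / (He - Me)

  where ``He, Hd`` are heart and ``Me, Md`` mediastinum count densities on
  the early/delayed images and ``k`` is the physical-decay coefficient
  ``2**(-(t_delayed - t_early)/half_life)``.  With the standard 15-min/3-h
  schedule and the 13.2232-h half-life of I-123, ``k ~= 0.8657``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "I123_HALF_LIFE_HOURS",
    "DEFAULT_T_EARLY_HOURS",
    "DEFAULT_T_DELAYED_HOURS",
    "StriatalCounts",
    "CardiacCounts",
    "IndexVector",
    "compute_sbr",
    "compute_pcr",
    "compute_ai",
    "compute_hm",
    "decay_coefficient",
    "compute_wr",
    "extract_dat_indices",
    "extract_mibg_indices",
]

#: Physical half-life of iodine-123 in hours.
I123_HALF_LIFE_HOURS = 13.2232
#: Standard early/delayed MIBG acquisition times post-injection (hours).
DEFAULT_T_EARLY_HOURS = 0.25
DEFAULT_T_DELAYED_HOURS = 3.0


@dataclass(frozen=True)
class StriatalCounts:
    """Mean counts per voxel in the striatal and occipital reference VOIs.

    ``caudate_voxels_*``/``putamen_voxels_*`` carry the VOI sizes so the
    per-side whole-striatum mean can be formed as a voxel-weighted union.
    Equal weights are assumed when the sizes are left at their default.
    """

    caudate_mean_left: float
    caudate_mean_right: float
    putamen_mean_left: float
    putamen_mean_right: float
    occipital_mean: float
    caudate_voxels_left: int = 1
    caudate_voxels_right: int = 1
    putamen_voxels_left: int = 1
    putamen_voxels_right: int = 1

    def __post_init__(self) -> None:
        if self.occipital_mean <= 0:
            raise ValueError("occipital reference mean must be positive")
        for name in (
            "caudate_mean_left",
            "caudate_mean_right",
            "putamen_mean_left",
            "putamen_mean_right",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def striatal_mean(self, side: str) -> float:
        """Voxel-weighted union mean of the caudate and putamen VOIs."""
        c = getattr(self, f"caudate_mean_{side}")
        p = getattr(self, f"putamen_mean_{side}")
        nc = getattr(self, f"caudate_voxels_{side}")
        np_ = getattr(self, f"putamen_voxels_{side}")
        return (c * nc + p * np_) / (nc + np_)


@dataclass(frozen=True)
class CardiacCounts:
    """Heart/mediastinum ROI count densities on the early and delayed images."""

    he: float
    hd: float
    me: float
    md: float
    k: float

    def __post_init__(self) -> None:
        if not 0 < self.k <= 1:
            raise ValueError("decay coefficient k must lie in (0, 1]")
        if self.he <= self.me:
            raise ValueError("heart counts must exceed mediastinum counts (He > Me)")


@dataclass
class IndexVector:
    """The six per-patient indices plus per-side audit detail."""

    hm_early: float | None = None
    hm_delay: float | None = None
    wr: float | None = None
    sbr: float | None = None
    pcr: float | None = None
    ai: float | None = None
    sbr_left: float | None = None
    sbr_right: float | None = None
    pcr_left: float | None = None
    pcr_right: float | None = None
    sbr_side_used: str | None = None
    pcr_side_used: str | None = None

    def as_dict(self) -> dict[str, float]:
        out = {}
        for f in ("hm_early", "hm_delay", "wr", "sbr", "pcr", "ai"):
            v = getattr(self, f)
            if v is not None:
                out[f] = v
        return out


def compute_sbr(striatal_mean: float, occipital_mean: float) -> float:
    """Background-subtracted striatal binding ratio ``(S - O) / O``."""
    if occipital_mean <= 0:
        raise ValueError("occipital reference mean must be positive")
    return (striatal_mean - occipital_mean) / occipital_mean


def compute_pcr(putamen_mean: float, caudate_mean: float) -> float:
    """Putamen-to-caudate mean-count ratio."""
    if caudate_mean <= 0:
        raise ValueError("caudate mean must be positive")
    return putamen_mean / caudate_mean


def compute_ai(sbr_left: float, sbr_right: float) -> float:
    """Asymmetry index |L - R| / mean(L, R); symmetric in its arguments."""
    mean = 0.5 * (sbr_left + sbr_right)
    if mean <= 0:
        raise ValueError("mean SBR must be positive to form an asymmetry index")
    return abs(sbr_left - sbr_right) / mean


def compute_hm(heart_density: float, mediastinum_density: float) -> float:
    """Heart-to-mediastinum count-density ratio."""
    if mediastinum_density <= 0:
        raise ValueError("mediastinum count density must be positive")
    return heart_density / mediastinum_density


def decay_coefficient(
    t_early: float, t_delayed: float, half_life: float = I123_HALF_LIFE_HOURS
) -> float:
    """Physical decay factor between the two acquisitions, ``2**(-dt/T_half)``."""
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    if t_delayed <= t_early:
        raise ValueError("delayed acquisition must come after the early one")
    return float(2.0 ** (-(t_delayed - t_early) / half_life))


def compute_wr(c: CardiacCounts) -> float:
    """Decay-corrected cardiac washout rate in percent."""
    return 100.0 * ((c.he - c.me) - (c.hd - c.md) / c.k) / (c.he - c.me)


def extract_dat_indices(counts: StriatalCounts) -> IndexVector:
    """SBR/PCR/AI from striatal VOI means; min-of-sides rule for SBR and PCR."""
    sbr_l = compute_sbr(counts.striatal_mean("left"), counts.occipital_mean)
    sbr_r = compute_sbr(counts.striatal_mean("right"), counts.occipital_mean)
    pcr_l = compute_pcr(counts.putamen_mean_left, counts.caudate_mean_left)
    pcr_r = compute_pcr(counts.putamen_mean_right, counts.caudate_mean_right)
    sbr_side = "left" if sbr_l <= sbr_r else "right"
    pcr_side = "left" if pcr_l <= pcr_r else "right"
    return IndexVector(
        sbr=min(sbr_l, sbr_r),
        pcr=min(pcr_l, pcr_r),
        ai=compute_ai(sbr_l, sbr_r),
        sbr_left=sbr_l,
        sbr_right=sbr_r,
        pcr_left=pcr_l,
        pcr_right=pcr_r,
        sbr_side_used=sbr_side,
        pcr_side_used=pcr_side,
    )


def extract_mibg_indices(pair) -> IndexVector:
    """H/M (Early), H/M (Delay) and WR from a paired early/delayed planar study.

    ``pair`` is a :class:`parkdx.phantom.PlanarPair`; count densities are ROI
    mean pixel intensities.
    """
    he = float(pair.early_image[pair.roi_map == pair.HEART].mean())
    me = float(pair.early_image[pair.roi_map == pair.MEDIASTINUM].mean())
    hd = float(pair.delayed_image[pair.roi_map == pair.HEART].mean())
    md = float(pair.delayed_image[pair.roi_map == pair.MEDIASTINUM].mean())
    k = decay_coefficient(pair.t_early, pair.t_delayed, pair.isotope_half_life)
    cc = CardiacCounts(he=he, hd=hd, me=me, md=md, k=k)
    return IndexVector(
        hm_early=compute_hm(he, me),
        hm_delay=compute_hm(hd, md),
        wr=compute_wr(cc),
    )
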