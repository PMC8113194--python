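"""Synthetic image-level inputs: a striatal SPECT phantom and paired planar
chest images, each carrying analytic ground-truth index values.

The phantom geometry is deliberately simple — parametric ellipsoids for the
caudate and putamen, a cuboid occipital reference slab, all on a fixed 64^3
grid with 4.4 mm voxels — because the indices only consume VOI/ROI mean
counts.  The VOI/ROI label maps are generated jointly with the images, so no
registration is involved.  Noise is additive Gaussian on intensities (clipped
at zero), with an optional Poisson mode for count-statistics flavour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantify import (
    DEFAULT_T_DELAYED_HOURS,
    DEFAULT_T_EARLY_HOURS,
    I123_HALF_LIFE_HOURS,
    StriatalCounts,
    compute_ai,
    decay_coefficient,
    extract_dat_indices,
)

__all__ = [
    "SpectPhantom",
    "PlanarPair",
    "generate_spect_phantom",
    "generate_planar_pair",
    "save_spect_phantom",
    "load_spect_phantom",
    "save_planar_pair",
    "load_planar_pair",
]

# VOI label codes in the SPECT phantom label volume.
SPECT_LABELS = {
    "background": 0,
    "left_caudate": 1,
    "right_caudate": 2,
    "left_putamen": 3,
    "right_putamen": 4,
    "occipital_reference": 5,
}

DEFAULT_SPECT_UPTAKE = {
    "left_caudate": 300.0,
    "right_caudate": 300.0,
    "left_putamen": 280.0,
    "right_putamen": 280.0,
    "occipital_reference": 100.0,
    "background": 20.0,
}


@dataclass
class SpectPhantom:
    """3D striatal phantom with its VOI label map and analytic truth indices."""

    volume: np.ndarray
    voi_map: np.ndarray
    voxel_size_mm: float
    uptake: dict[str, float]
    truth: dict[str, float]

    def to_striatal_counts(self) -> StriatalCounts:
        """Measure VOI mean counts (and VOI sizes) from the image pair."""
        means = {}
        sizes = {}
        for name, code in SPECT_LABELS.items():
            if name == "background":
                continue
            mask = self.voi_map == code
            means[name] = float(self.volume[mask].mean())
            sizes[name] = int(mask.sum())
        return StriatalCounts(
            caudate_mean_left=means["left_caudate"],
            caudate_mean_right=means["right_caudate"],
            putamen_mean_left=means["left_putamen"],
            putamen_mean_right=means["right_putamen"],
            occipital_mean=means["occipital_reference"],
            caudate_voxels_left=sizes["left_caudate"],
            caudate_voxels_right=sizes["right_caudate"],
            putamen_voxels_left=sizes["left_putamen"],
            putamen_voxels_right=sizes["right_putamen"],
        )


@dataclass
class PlanarPair:
    """Early/delayed planar chest images with a shared heart/mediastinum ROI map."""

    HEART = 1
    MEDIASTINUM = 2

    early_image: np.ndarray
    delayed_image: np.ndarray
    roi_map: np.ndarray
    t_early: float = DEFAULT_T_EARLY_HOURS
    t_delayed: float = DEFAULT_T_DELAYED_HOURS
    isotope_half_life: float = I123_HALF_LIFE_HOURS
    truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_delayed <= self.t_early:
            raise ValueError("t_delayed must exceed t_early")
        if self.isotope_half_life <= 0:
            raise ValueError("isotope half-life must be positive")
        for code in (self.HEART, self.MEDIASTINUM):
            if not (self.roi_map == code).any():
                raise ValueError(f"ROI label {code} is empty")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((xx - center[2]) / radii[2]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[0]) / radii[0]) ** 2
    ) <= 1.0


def _build_spect_geometry(shape=(64, 64, 64)) -> np.ndarray:
    """Fixed template VOI map: ellipsoidal caudate/putamen, occipital slab."""
    voi = np.zeros(shape, dtype=np.int16)
    # slices: z = axial index, y = anterior(low)-posterior(high), x = left-right
    voi[_ellipsoid_mask(shape, (32, 26, 24), (3.0, 4.0, 2.5))] = SPECT_LABELS[
        "left_caudate"
    ]
    voi[_ellipsoid_mask(shape, (32, 26, 40), (3.0, 4.0, 2.5))] = SPECT_LABELS[
        "right_caudate"
    ]
    voi[_ellipsoid_mask(shape, (32, 34, 21), (3.0, 5.5, 3.0))] = SPECT_LABELS[
        "left_putamen"
    ]
    voi[_ellipsoid_mask(shape, (32, 34, 43), (3.0, 5.5, 3.0))] = SPECT_LABELS[
        "right_putamen"
    ]
    voi[28:37, 52:58, 20:45] = SPECT_LABELS["occipital_reference"]
    return voi


def _spect_truth(uptake: dict[str, float], voi: np.ndarray) -> dict[str, float]:
    """Analytic SBR/PCR/AI implied by the configured uptakes and VOI sizes."""
    occ = uptake["occipital_reference"]
    sizes = {n: int((voi == c).sum()) for n, c in SPECT_LABELS.items()}
    truth: dict[str, float] = {}
    sbr_sides = {}
    for side in ("left", "right"):
        nc, npn = sizes[f"{side}_caudate"], sizes[f"{side}_putamen"]
        union = (uptake[f"{side}_caudate"] * nc + uptake[f"{side}_putamen"] * npn) / (
            nc + npn
        )
        sbr_sides[side] = (union - occ) / occ
        truth[f"sbr_{side}"] = sbr_sides[side]
        truth[f"pcr_{side}"] = uptake[f"{side}_putamen"] / uptake[f"{side}_caudate"]
    truth["sbr"] = min(sbr_sides["left"], sbr_sides["right"])
    truth["pcr"] = min(truth["pcr_left"], truth["pcr_right"])
    mean_sbr = 0.5 * (sbr_sides["left"] + sbr_sides["right"])
    # AI is undefined when the mean SBR is not positive (striatal uptake at
    # or below the reference level on both sides)
    truth["ai"] = (
        compute_ai(sbr_sides["left"], sbr_sides["right"])
        if mean_sbr > 0
        else float("nan")
    )
    return truth


def generate_spect_phantom(
    uptake: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    voxel_size_mm: float = 4.4,
    poisson: bool = False,
) -> SpectPhantom:
    """Build a striatal phantom whose VOI means equal the configured uptakes.

    ``uptake`` maps the structure names of :data:`SPECT_LABELS` to mean count
    levels.  At ``noise_sd = 0`` (and ``poisson=False``) the voxel values
    inside each VOI equal the configured uptake exactly, so extraction
    round-trips the analytic ``truth`` to machine precision.
    """
    up = dict(DEFAULT_SPECT_UPTAKE)
    if uptake:
        unknown = set(uptake) - set(up)
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")
        up.update(uptake)
    if up["occipital_reference"] <= 0:
        raise ValueError("occipital reference uptake must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    voi = _build_spect_geometry()
    volume = np.full(voi.shape, up["background"], dtype=float)
    for name, code in SPECT_LABELS.items():
        if name == "background":
            continue
        volume[voi == code] = up[name]

    rng = np.random.default_rng(seed)
    if poisson:
        volume = rng.poisson(np.clip(volume, 0, None)).astype(float)
    if noise_sd > 0:
        volume = np.clip(volume + rng.normal(0.0, noise_sd, volume.shape), 0.0, None)

    return SpectPhantom(
        volume=volume,
        voi_map=voi,
        voxel_size_mm=voxel_size_mm,
        uptake=up,
        truth=_spect_truth(up, voi),
    )


def _planar_truth(
    heart_early, mediastinum_early, heart_delayed, mediastinum_delayed, k
) -> dict[str, float]:
    he, me = heart_early, mediastinum_early
    hd, md = heart_delayed, mediastinum_delayed
    return {
        "hm_early": he / me,
        "hm_delay": hd / md,
        "wr": 100.0 * ((he - me) - (hd - md) / k) / (he - me),
    }


def generate_planar_pair(
    heart_early: float = 260.0,
    mediastinum_early: float = 100.0,
    heart_delayed: float = 230.0,
    mediastinum_delayed: float = 90.0,
    t_early: float = DEFAULT_T_EARLY_HOURS,
    t_delayed: float = DEFAULT_T_DELAYED_HOURS,
    half_life: float = I123_HALF_LIFE_HOURS,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
) -> PlanarPair:
    """Build an early/delayed planar pair with rectangular heart and
    mediastinum ROIs and analytic H/M and WR truth values."""
    for name, v in {
        "heart_early": heart_early,
        "mediastinum_early": mediastinum_early,
        "heart_delayed": heart_delayed,
        "mediastinum_delayed": mediastinum_delayed,
    }.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if t_delayed <= t_early:
        raise ValueError("t_delayed must exceed t_early")
    if heart_early <= mediastinum_early:
        raise ValueError("early heart density must exceed the mediastinum (He > Me)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    roi = np.zeros(shape, dtype=np.int16)
    h0, h1 = shape[0] // 2, shape[0] // 2 + shape[0] // 6
    roi[h0:h1, shape[1] // 4 : shape[1] // 4 + shape[1] // 6] = PlanarPair.HEART
    roi[shape[0] // 8 : shape[0] // 4, 7 * shape[1] // 16 : 9 * shape[1] // 16] = (
        PlanarPair.MEDIASTINUM
    )

    background = 0.2 * mediastinum_early
    early = np.full(shape, background, dtype=float)
    delayed = np.full(shape, 0.2 * mediastinum_delayed, dtype=float)
    early[roi == PlanarPair.HEART] = heart_early
    early[roi == PlanarPair.MEDIASTINUM] = mediastinum_early
    delayed[roi == PlanarPair.HEART] = heart_delayed
    delayed[roi == PlanarPair.MEDIASTINUM] = mediastinum_delayed

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        early = np.clip(early + rng.normal(0.0, noise_sd, shape), 0.0, None)
        delayed = np.clip(delayed + rng.normal(0.0, noise_sd, shape), 0.0, None)

    k = decay_coefficient(t_early, t_delayed, half_life)
    return PlanarPair(
        early_image=early,
        delayed_image=delayed,
        roi_map=roi,
        t_early=t_early,
        t_delayed=t_delayed,
        isotope_half_life=half_life,
        truth=_planar_truth(
            heart_early, mediastinum_early, heart_delayed, mediastinum_delayed, k
        ),
    )


def quantify_phantom(phantom: SpectPhantom):
    """Extract the DAT indices from a phantom via its VOI means."""
    return extract_dat_indices(phantom.to_striatal_counts())


# ---------------------------------------------------------------------------
# File round-trips (NIfTI volumes / TIFF planar images + JSON truth sidecars)

def save_spect_phantom(phantom: SpectPhantom, directory) -> None:
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([phantom.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(phantom.volume, affine), directory / "volume.nii")
    nib.save(
        nib.Nifti1Image(phantom.voi_map.astype(np.int16), affine),
        directory / "voi_map.nii",
    )
    (directory / "truth.json").write_text(
        json.dumps({"uptake": phantom.uptake, "truth": phantom.truth}, indent=2)
    )


def load_spect_phantom(directory) -> SpectPhantom:
    import nibabel as nib

    directory = Path(directory)
    vol_img = nib.load(directory / "volume.nii")
    voi_img = nib.load(directory / "voi_map.nii")
    meta = json.loads((directory / "truth.json").read_text())
    return SpectPhantom(
        volume=np.asarray(vol_img.dataobj, dtype=float),
        voi_map=np.asarray(voi_img.dataobj, dtype=np.int16),
        voxel_size_mm=float(vol_img.affine[0, 0]),
        uptake=meta["uptake"],
        truth=meta["truth"],
    )


def save_planar_pair(pair: PlanarPair, directory) -> None:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "early.tif", pair.early_image.astype(np.float32))
    tifffile.imwrite(directory / "delayed.tif", pair.delayed_image.astype(np.float32))
    tifffile.imwrite(directory / "roi_map.tif", pair.roi_map.astype(np.int16))
    (directory / "truth.json").write_text(
        json.dumps(
            {
                "t_early": pair.t_early,
                "t_delayed": pair.t_delayed,
                "isotope_half_life": pair.isotope_half_life,
                "truth": pair.truth,
            },
            indent=2,
        )
    )


def load_planar_pair(directory) -> PlanarPair:
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "truth.json").read_text())
    return PlanarPair(
        early_image=tifffile.imread(directory / "early.tif").astype(float),
        delayed_image=tifffile.imread(directory / "delayed.tif").astype(float),
        roi_map=tifffile.imread(directory / "roi_map.tif").astype(np.int16),
        t_early=meta["t_early"],
        t_delayed=meta["t_delayed"],
        isotope_half_life=meta["isotope_half_life"],
        truth=meta["truth"],
    )
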