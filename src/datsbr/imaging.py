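"""PET volume handling and regional SBR extraction.

The quantification chain mirrors standard FP-CIT processing: a standardized
uptake value ratio (SUVR) map is formed by dividing the PET volume by the
mean uptake in an occipital white-matter reference mask; caudate and putamen
masks are split into anterior/posterior subregions by a deterministic
k-means on voxel world coordinates; striatal masks are eroded by one voxel
(6-connectivity) to limit partial-volume contamination; and the regional
specific binding ratio (SBR) is the median SUVR inside the (eroded) mask.
The substantia nigra is extracted without erosion — its mask is already
small — and bilateral SBRs pool left and right voxels before taking the
median.

By default the SBR is the median SUVR itself; the conventional
``(target/reference − 1)`` variant is available via ``convention``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import nibabel as nib
from scipy import ndimage

from .regions import REGIONS

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "EmptyMaskError",
    "compute_suvr_map",
    "erode_mask",
    "split_anterior_posterior",
    "extract_sbr",
    "extract_regional_sbr",
]


class EmptyMaskError(ValueError):
    """A mask required for extraction is empty (possibly after erosion)."""

    def __init__(self, name: str, detail: str = ""):
        self.mask_name = name
        msg = f"mask '{name}' is empty"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass
class VolumeImage:
    """A 3D scalar grid with its voxel-to-world affine (RAS+)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(path))


@dataclass
class LabelVolume:
    """Integer-labelled ROI volume with a label dictionary.

    ``labels`` maps each integer id to ``{"region": str, "side": "L"|"R"|"NA"}``.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=float)

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def mask_for(self, region: str, side: str | None = None) -> np.ndarray:
        """Boolean mask pooling all labels matching region (and side)."""
        out = np.zeros(self.data.shape, dtype=bool)
        for lid, meta in self.labels.items():
            if meta["region"] != region:
                continue
            if side is not None and meta["side"] != side:
                continue
            out |= self.data == lid
        return out

    @classmethod
    def from_nifti(cls, path, labels_json) -> "LabelVolume":
        img = nib.load(str(path))
        arr = np.asarray(img.get_fdata()).round().astype(np.int32)
        with open(labels_json, encoding="utf-8") as fh:
            raw = json.load(fh)
        labels = {int(k): v for k, v in raw.items()}
        return cls(arr, img.affine, labels)

    def to_nifti(self, path, labels_json=None) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine),
                 str(path))
        if labels_json is not None:
            with open(labels_json, "w", encoding="utf-8") as fh:
                json.dump({str(k): v for k, v in self.labels.items()}, fh,
                          indent=2)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_suvr_map(pet: VolumeImage, reference_mask: np.ndarray,
                     summary: str = "mean",
                     mask_name: str = "reference") -> VolumeImage:
    """Divide the PET volume by the reference-region uptake summary.

    ``summary`` is ``"mean"`` (default, conventional SUVR referencing) or
    ``"median"``.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != pet.data.shape:
        raise ValueError("reference mask grid does not match PET grid")
    if not reference_mask.any():
        raise EmptyMaskError(mask_name)
    vals = pet.data[reference_mask]
    ref = float(np.mean(vals) if summary == "mean" else np.median(vals))
    if ref <= 0:
        raise ValueError(
            f"reference summary over mask '{mask_name}' is non-positive ({ref:g})")
    return VolumeImage(pet.data / ref, pet.affine)


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # faces only


def erode_mask(mask: np.ndarray, iterations: int = 1,
               region: str = "mask") -> np.ndarray:
    """Erode a binary mask with the 6-connected structuring element.

    Raises :class:`EmptyMaskError` if erosion empties the mask; callers
    that prefer to fall back to the uneroded mask must do so explicitly.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_6,
                                    iterations=iterations)
    if not eroded.any():
        raise EmptyMaskError(region, f"erosion by {iterations} emptied it")
    return eroded


def split_anterior_posterior(mask: np.ndarray, affine: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into anterior/posterior halves by k-means (k=2).

    Voxel world coordinates (RAS+, y increases anteriorly) are clustered
    with a deterministic Lloyd iteration: centroids start at the two mask
    voxels extreme along y, assignment ties break toward the anterior
    centroid, and iteration runs to convergence. The cluster whose centroid
    has the larger y is returned first (anterior).
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) < 2:
        raise ValueError("mask must contain at least 2 voxels to split")
    affine = np.asarray(affine, dtype=float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    if np.allclose(world, world[0]):
        raise ValueError("degenerate mask geometry: all voxels coincide")

    order = np.argsort(world[:, 1], kind="stable")
    c_post = world[order[0]].astype(float)   # most posterior voxel
    c_ant = world[order[-1]].astype(float)   # most anterior voxel
    if np.allclose(c_post, c_ant):
        raise ValueError("degenerate mask geometry along the A-P axis")

    assign = None
    for _ in range(200):
        d_ant = ((world - c_ant) ** 2).sum(axis=1)
        d_post = ((world - c_post) ** 2).sum(axis=1)
        new_assign = d_ant <= d_post  # ties -> anterior
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        if assign.all() or not assign.any():
            break  # one cluster collapsed; keep previous centroids' split
        c_ant = world[assign].mean(axis=0)
        c_post = world[~assign].mean(axis=0)

    anterior = np.zeros_like(mask)
    posterior = np.zeros_like(mask)
    anterior[tuple(idx[assign].T)] = True
    posterior[tuple(idx[~assign].T)] = True
    # orient by centroid y
    if anterior.any() and posterior.any():
        y_a = world[assign][:, 1].mean()
        y_p = world[~assign][:, 1].mean()
        if y_a < y_p:
            anterior, posterior = posterior, anterior
    return anterior, posterior


def extract_sbr(suvr: VolumeImage, mask: np.ndarray,
                region: str = "roi") -> float:
    """Median SUVR inside the mask (the regional SBR)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError(region)
    return float(np.median(suvr.data[mask]))


def extract_regional_sbr(
    pet: VolumeImage,
    labels: LabelVolume,
    reference_region: str = "occipital_wm",
    erode_iterations: int = 1,
    convention: str = "suvr",
    reference_summary: str = "mean",
    subject_id: str | None = None,
) -> dict:
    """Run the full extraction for one subject.

    Caudate and putamen masks are split per hemisphere into anterior and
    posterior subregions, eroded, and their median SUVR extracted; the
    substantia nigra is extracted uneroded. Bilateral SBRs pool left and
    right voxels. ``convention="suvr_minus_1"`` subtracts 1 from every SBR.

    Returns a flat dict: per-region bilateral values under the region name
    (``AP``, ``PP``, ``AC``, ``PC``, ``SN``) and per-hemisphere values under
    ``{region}_{L|R}``, plus the reference level used.
    """
    ref_mask = labels.mask_for(reference_region)
    if not ref_mask.any():
        raise EmptyMaskError(reference_region)
    ref_vals = pet.data[ref_mask]
    ref_level = float(np.mean(ref_vals) if reference_summary == "mean"
                      else np.median(ref_vals))
    suvr = compute_suvr_map(pet, ref_mask, summary=reference_summary,
                            mask_name=reference_region)

    side_masks: dict[str, np.ndarray] = {}
    for struct, (ant, post) in (("putamen", ("AP", "PP")),
                                ("caudate", ("AC", "PC"))):
        for side in ("L", "R"):
            m = labels.mask_for(struct, side)
            if not m.any():
                raise EmptyMaskError(f"{struct}_{side}")
            a, p = split_anterior_posterior(m, labels.affine)
            side_masks[f"{ant}_{side}"] = erode_mask(
                a, erode_iterations, region=f"{ant}_{side}")
            side_masks[f"{post}_{side}"] = erode_mask(
                p, erode_iterations, region=f"{post}_{side}")
    for side in ("L", "R"):
        m = labels.mask_for("SN", side)
        if not m.any():
            raise EmptyMaskError(f"SN_{side}")
        side_masks[f"SN_{side}"] = m  # no erosion for the nigral ROI

    offset = 1.0 if convention == "suvr_minus_1" else 0.0
    out: dict = {"reference_level": ref_level}
    if subject_id is not None:
        out["subject_id"] = subject_id
    for r in REGIONS:
        left = side_masks[f"{r}_L"]
        right = side_masks[f"{r}_R"]
        out[f"{r}_L"] = extract_sbr(suvr, left, f"{r}_L") - offset
        out[f"{r}_R"] = extract_sbr(suvr, right, f"{r}_R") - offset
        out[r] = extract_sbr(suvr, left | right, r) - offset
    return out
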