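"""Viable tumor volume quantification from paired contrast-enhanced volumes.

Implements the volumetric qEASL measurement: subtract the unenhanced from the
arterial-phase enhanced volume to obtain an enhancement map, estimate the
enhancement of healthy liver parenchyma from a small set of reference points,
and segment the voxels of the whole-tumor mask (Seg1) whose enhancement
exceeds that parenchyma threshold. The supra-threshold subset (Seg2) is the
viable tumor; its physical volume in cm^3 is the viable tumor volume (VTV).

Whole-tumor segmentation (Seg1) is an input: it is produced interactively in
clinical workflows and by the phantom generator in tests. Enhanced and
unenhanced volumes must be co-registered on the same grid; registration is a
precondition, not a service of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DimensionMismatchError, ValidationError

__all__ = [
    "ScalarVolume3D",
    "BinaryMask3D",
    "ReferencePointSet",
    "ViableVolumeResult",
    "subtract_background",
    "parenchyma_threshold",
    "segment_viable",
    "mask_volume",
    "quantify_viable_tumor",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "load_reference_points",
]


@dataclass
class ScalarVolume3D:
    """A 3D scalar intensity grid with physical voxel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("volume must be a 3D array with each axis of length >= 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive values (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume3D | BinaryMask3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class BinaryMask3D:
    """A 3D binary mask sharing the grid of a companion volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValidationError("mask must be a 3D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive values (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ReferencePointSet:
    """Healthy-parenchyma sampling sites in voxel coordinates.

    Each point is averaged over a cubic neighborhood of the given radius
    (radius 0 = the single voxel, radius 1 = the 3x3x3 cube) before the
    per-point values are themselves averaged into the threshold.
    """

    points: list[tuple[int, int, int]]
    neighborhood_radius_voxels: int = 1

    def __post_init__(self):
        self.points = [tuple(int(c) for c in p) for p in self.points]
        if len(self.points) < 3:
            raise ValidationError("at least 3 reference points are required")
        if any(len(p) != 3 for p in self.points):
            raise ValidationError("reference points must be integer voxel triplets")
        if self.neighborhood_radius_voxels < 0:
            raise ValidationError("neighborhood radius must be non-negative")

    def validate_for(self, volume: ScalarVolume3D, seg1: BinaryMask3D | None = None) -> None:
        shape = volume.shape
        for p in self.points:
            if any(c < 0 or c >= n for c, n in zip(p, shape)):
                raise IndexError(f"reference point {p} lies outside the volume bounds {shape}")
            if seg1 is not None and seg1.values[p] == 1:
                raise ValidationError(f"reference point {p} lies inside the tumor mask")


@dataclass
class ViableVolumeResult:
    """Output of the full quantification: threshold, Seg2 and VTV (cm^3)."""

    threshold: float
    seg2: BinaryMask3D
    vtv_cm3: float
    seg1_volume_cm3: float = field(default=float("nan"))

    def __post_init__(self):
        if self.vtv_cm3 < 0:
            raise ValidationError("viable tumor volume cannot be negative")


def _check_same_grid(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise DimensionMismatchError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise DimensionMismatchError(f"{what}: spacing mismatch {a.spacing} vs {b.spacing}")


def subtract_background(enhanced: ScalarVolume3D, unenhanced: ScalarVolume3D) -> ScalarVolume3D:
    """Voxelwise enhancement map: enhanced minus unenhanced (may be negative)."""
    _check_same_grid(enhanced, unenhanced, "subtract_background")
    return ScalarVolume3D(
        enhanced.values - unenhanced.values, spacing=enhanced.spacing, origin=enhanced.origin
    )


def parenchyma_threshold(enh_map: ScalarVolume3D, refs: ReferencePointSet) -> float:
    """Mean parenchyma enhancement over the reference points.

    Each point contributes the mean of its cubic neighborhood, clipped to the
    volume bounds; the threshold is the arithmetic mean of the per-point values.
    """
    refs.validate_for(enh_map)
    r = refs.neighborhood_radius_voxels
    shape = enh_map.shape
    per_point = []
    for p in refs.points:
        sl = tuple(
            slice(max(c - r, 0), min(c + r + 1, n)) for c, n in zip(p, shape)
        )
        per_point.append(float(enh_map.values[sl].mean()))
    return float(np.mean(per_point))


def segment_viable(enh_map: ScalarVolume3D, seg1: BinaryMask3D, threshold: float) -> BinaryMask3D:
    """Seg2: voxels of Seg1 whose enhancement is strictly above the threshold."""
    _check_same_grid(enh_map, seg1, "segment_viable")
    out = (seg1.values == 1) & (enh_map.values > threshold)
    return BinaryMask3D(out.astype(np.uint8), spacing=seg1.spacing)


def mask_volume(mask: BinaryMask3D) -> float:
    """Physical volume of a mask in cm^3 (voxel count x voxel volume)."""
    return mask.count() * mask.voxel_volume_mm3 / 1000.0


def quantify_viable_tumor(
    enhanced: ScalarVolume3D,
    unenhanced: ScalarVolume3D,
    seg1: BinaryMask3D,
    refs: ReferencePointSet,
) -> ViableVolumeResult:
    """Full qEASL quantification: enhancement map -> threshold -> Seg2 -> VTV."""
    _check_same_grid(enhanced, seg1, "quantify_viable_tumor")
    enh_map = subtract_background(enhanced, unenhanced)
    refs.validate_for(enh_map, seg1)
    thr = parenchyma_threshold(enh_map, refs)
    seg2 = segment_viable(enh_map, seg1, thr)
    return ViableVolumeResult(
        threshold=thr,
        seg2=seg2,
        vtv_cm3=mask_volume(seg2),
        seg1_volume_cm3=mask_volume(seg1),
    )


# ---------------------------------------------------------------------------
# NIfTI and CSV I/O


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(abs(affine[i, i])) for i in range(3))


def load_volume(path) -> ScalarVolume3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D NIfTI volume, got shape {data.shape}")
    return ScalarVolume3D(data, spacing=_spacing_from_affine(img.affine))


def load_mask(path) -> BinaryMask3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return BinaryMask3D((data > 0.5).astype(np.uint8), spacing=_spacing_from_affine(img.affine))


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(vol: ScalarVolume3D, path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing)), str(path))


def save_mask(mask: BinaryMask3D, path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing)), str(path))


def load_reference_points(path, neighborhood_radius_voxels: int = 1) -> ReferencePointSet:
    """Read reference points from a CSV with integer 0-based columns x,y,z."""
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValidationError(f"reference point CSV lacks columns: {sorted(missing)}")
    pts = [(int(r.x), int(r.y), int(r.z)) for r in df.itertuples()]
    return ReferencePointSet(pts, neighborhood_radius_voxels=neighborhood_radius_voxels)
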