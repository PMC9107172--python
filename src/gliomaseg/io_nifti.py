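"""NIfTI input/output with explicit geometry handling.

Volumes are always reoriented to the closest canonical (RAS) axis order on
load, so that the first voxel axis is the anatomical left-right axis — the
hemisphere-symmetry pipeline mirrors along that axis without further checks.

Non-contiguous acquisitions (slice thickness smaller than the center-to-center
slice spacing) are represented explicitly: ``spacing[2]`` is the slice
thickness and ``slice_gap`` the unimaged distance between consecutive slices.
On disk this maps to pixdim (thickness) versus the affine z column
(center-to-center spacing). No resampling is ever performed on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LabelMask",
    "GeometryReport",
    "LABEL_BACKGROUND",
    "LABEL_NECROTIC",
    "LABEL_EDEMA",
    "VALID_LABELS",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "check_geometry_compatible",
]

LABEL_BACKGROUND = 0
LABEL_NECROTIC = 1
LABEL_EDEMA = 2
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_NECROTIC, LABEL_EDEMA})

#: spacing components closer than this (mm) are considered equal
SPACING_TOL_MM = 1e-3


def _default_affine(spacing, slice_gap):
    aff = np.diag([spacing[0], spacing[1], spacing[2] + slice_gap, 1.0])
    return aff


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing in mm.

    ``spacing`` holds (dx, dy, dz) where dz is the slice *thickness*;
    ``slice_gap`` is the extra mm between acquired slice centers beyond dz
    (0 for contiguous acquisitions). The axis convention is fixed:
    x = left-to-right, y = posterior-to-anterior, z = inferior-to-superior.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_gap: float = 0.0
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        if any(n <= 0 for n in self.data.shape):
            raise ValueError(f"degenerate shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.slice_gap = float(self.slice_gap)
        if self.slice_gap < 0:
            raise ValueError(f"slice_gap must be >= 0, got {self.slice_gap}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"volume contains {n_nan} NaN voxel(s)")
        if self.affine is None:
            self.affine = _default_affine(self.spacing, self.slice_gap)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape

    @property
    def effective_spacing(self):
        """Center-to-center spacing (dx, dy, dz + slice_gap) for distances in mm."""
        dx, dy, dz = self.spacing
        return (dx, dy, dz + self.slice_gap)

    def voxel_volume_mm3(self):
        """Imaged volume per voxel (slice gap excluded — those mm were never imaged)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class LabelMask:
    """Integer label volume sharing a Volume3D's geometry.

    Labels: 0 background, 1 necrotic, 2 edema. The whole-tumor mask is
    ``labels >= 1`` by definition. ``undifferentiated`` marks masks whose
    tumor components were not separated by the producing algorithm (the
    region-growing method outputs the whole tumor only).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    slice_gap: float = 0.0
    affine: np.ndarray | None = None
    undifferentiated: bool = False

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.rint(labels), atol=0, rtol=0):
                bad = np.unique(labels[labels != np.rint(labels)])[:5]
                raise ValueError(f"non-integer label values, e.g. {bad.tolist()}")
            labels = np.rint(labels).astype(np.int16)
        self.labels = labels.astype(np.int16, copy=False)
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - VALID_LABELS)
        if unknown:
            raise ValueError(f"unknown label value(s) {unknown}; expected subset of {sorted(VALID_LABELS)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.slice_gap = float(self.slice_gap)
        if self.affine is None:
            self.affine = _default_affine(self.spacing, self.slice_gap)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.labels.shape

    def whole_tumor(self):
        return self.labels >= 1

    def edema(self):
        return self.labels == LABEL_EDEMA

    def necrotic(self):
        return self.labels == LABEL_NECROTIC


@dataclass
class GeometryReport:
    """Result of a geometry-compatibility check between two volumes/masks."""

    compatible: bool
    mismatches: list[str] = field(default_factory=list)

    def __bool__(self):
        return self.compatible


def _load_canonical(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises various format errors
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        extra = img.shape[3:]
        raise ValueError(
            f"{path}: expected a 3D volume, got {len(img.shape)}D with extra dimension(s) {extra}"
        )
    return nib.as_closest_canonical(img)


def _geometry_from(img):
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine, dtype=np.float64)
    col_norms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    # thickness lives in pixdim; center-to-center spacing in the affine.
    dz_centers = float(col_norms[2])
    thickness = zooms[2]
    gap = dz_centers - thickness
    if gap < SPACING_TOL_MM:
        gap = 0.0
    spacing = (zooms[0], zooms[1], thickness)
    return spacing, gap, affine


def read_volume(path) -> Volume3D:
    """Read a NIfTI volume, normalized to canonical (RAS) axis order.

    Rejects 4D inputs and volumes containing NaN. The slice gap is derived
    as (center-to-center z spacing from the affine) minus (slice thickness
    from pixdim) when positive.
    """
    img = _load_canonical(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing, gap, affine = _geometry_from(img)
    return Volume3D(data=data, spacing=spacing, slice_gap=gap, affine=affine)


def read_mask(path, reference: Volume3D | None = None) -> LabelMask:
    """Read a NIfTI label mask, validating labels and (optionally) geometry.

    Labels must be integer-valued members of {0, 1, 2}; non-integer data is
    rejected rather than rounded. If ``reference`` is given the mask shape
    must match it.
    """
    img = _load_canonical(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if np.isnan(data).any():
        raise ValueError(f"{path}: mask contains NaN voxels")
    spacing, gap, affine = _geometry_from(img)
    mask = LabelMask(labels=data, spacing=spacing, slice_gap=gap, affine=affine)
    if reference is not None and mask.shape != reference.shape:
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match reference shape {reference.shape}"
        )
    return mask


def _write(data, spacing, slice_gap, affine, path, dtype):
    affine = np.asarray(affine, dtype=np.float64).copy()
    col_norm = np.sqrt((affine[:3, 2] ** 2).sum())
    want = spacing[2] + slice_gap
    if col_norm > 0 and abs(col_norm - want) > 1e-9:
        affine[:3, 2] *= want / col_norm
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume; read_volume(write_volume(v)) reproduces data and geometry."""
    _write(vol.data, vol.spacing, vol.slice_gap, vol.affine, path, np.float64)


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask; round-trips bit-exactly through read_mask."""
    _write(mask.labels, mask.spacing, mask.slice_gap, mask.affine, path, np.uint8)


def check_geometry_compatible(a, b) -> GeometryReport:
    """Report whether two volumes/masks share shape and spacing.

    Compatible iff shapes are equal and each spacing component agrees within
    1e-3 mm. Never raises: the report enumerates every mismatching attribute
    (this is the guard that catches mixing acquisitions of different matrix
    dimension, e.g. a 512x464x160 3D series against a 512x448x20 2D series).
    """
    mismatches = []
    if a.shape != b.shape:
        mismatches.append(f"shape: {a.shape} vs {b.shape}")
    for name, sa, sb in zip(("dx", "dy", "dz"), a.spacing, b.spacing):
        if abs(sa - sb) > SPACING_TOL_MM:
            mismatches.append(f"spacing {name}: {sa} vs {sb} mm")
    ga, gb = getattr(a, "slice_gap", 0.0), getattr(b, "slice_gap", 0.0)
    if abs(ga - gb) > SPACING_TOL_MM:
        mismatches.append(f"slice_gap: {ga} vs {gb} mm")
    return GeometryReport(compatible=not mismatches, mismatches=mismatches)
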