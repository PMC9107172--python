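"""Hemisphere-symmetry region growing for whole-tumor segmentation.

The method rests on two anatomical assumptions: (1) the tumor sits in one
hemisphere only, and (2) the healthy brain is approximately mirror-symmetric
about the interhemispheric (midsagittal) plane. The pipeline is:

1. ``align_vertical`` — find the in-plane rotation and midline column that
   maximize mirror similarity of the head mask, so the two hemispheres can
   be split by a single voxel column.
2. ``split_hemispheres`` — cut the aligned volume at the midline.
3. ``asymmetry_map`` — subtract each hemisphere from the mirrored other one;
   voxels whose absolute difference exceeds a robust noise threshold form
   the tumor candidate region, and the side holding most of that mass is
   declared the tumor side.
4. Per axial slice intersecting the candidate region: ``contrast_stretch``
   (percentile rescale to [0, 1]), ``select_seed`` (brightest candidate
   voxel) and ``region_grow`` (connected voxels within an intensity
   tolerance of the seed).
5. ``segment_rg`` unions the per-slice masks, fills enclosed holes (the
   non-enhancing core inside the bright edema ring belongs to the whole
   tumor) and maps the result back through the inverse alignment.

When the asymmetry mass is nearly balanced between the sides — the signature
of a bilateral or midline tumor, for which assumption (1) fails — the run is
flagged ``bilateral_suspect`` instead of silently returning one hemisphere's
half of the lesion. The method outputs the whole tumor only; it cannot
separate edema from the necrotic core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_nifti import LABEL_EDEMA, LabelMask, Volume3D

__all__ = [
    "RGParams",
    "AlignmentResult",
    "AsymmetryResult",
    "RGDiagnostics",
    "align_vertical",
    "split_hemispheres",
    "asymmetry_map",
    "contrast_stretch",
    "select_seed",
    "region_grow",
    "segment_rg",
]

logger = logging.getLogger(__name__)

ROTATION_RANGE_DEG = 20.0
ROTATION_STEP_DEG = 0.5
#: MAD-to-sigma factor for a Gaussian
MAD_SCALE = 1.4826


@dataclass
class RGParams:
    """Tunables of the region-growing pipeline.

    intensity_tolerance: a neighbor joins the region iff its stretched
        intensity is within this fraction of unit range of the seed's.
    connectivity: in-plane neighborhood, 4 (faces) or 8 (faces + diagonals).
    stretch_percentiles: in-brain percentiles mapped to 0 and 1.
    asymmetry_threshold: multiple of the robust (MAD-based) noise scale a
        left-right difference must exceed to count as tumor candidate.
    bilateral_confidence_floor: minimum fraction of asymmetry mass on the
        winning side; below it the run is flagged bilateral-suspect.
    rim_exclusion: in-plane voxels eroded off the brain mask before
        thresholding the asymmetry — sub-voxel alignment residuals create
        spurious differences along the head outline that must not seed the
        growth.
    candidate_min_area: smallest in-plane candidate component (voxels) that
        may seed growth on a slice; isolated supra-threshold noise voxels
        must not seed (a seed on normal brain grows the whole brain).
    """

    intensity_tolerance: float = 0.2
    connectivity: int = 8
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    asymmetry_threshold: float = 3.0
    bilateral_confidence_floor: float = 0.65
    fill_holes: bool = True
    rim_exclusion: int = 3
    candidate_min_area: int = 20

    def __post_init__(self):
        if not 0 < self.intensity_tolerance < 1:
            raise ValueError("intensity_tolerance must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        lo, hi = self.stretch_percentiles
        if not lo < hi:
            raise ValueError("stretch percentiles must satisfy p_low < p_high")
        if self.asymmetry_threshold <= 0 or self.bilateral_confidence_floor <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class AlignmentResult:
    rotation_deg: float
    midline_x: int
    aligned: Volume3D
    score: float = 0.0

    def __post_init__(self):
        if abs(self.rotation_deg) > 45:
            raise ValueError(f"implausible rotation {self.rotation_deg} deg")
        nx = self.aligned.shape[0]
        if not 0 < self.midline_x < nx - 1:
            raise ValueError(f"midline {self.midline_x} at or beyond volume edge (nx={nx})")


@dataclass
class AsymmetryResult:
    diff_left: np.ndarray
    diff_right: np.ndarray
    tumor_side: str
    candidate_region: np.ndarray  # full aligned-volume shape, bool
    confidence: float
    noise_sigma: float = 0.0


@dataclass
class RGDiagnostics:
    rotation_deg: float
    midline_x: int
    tumor_side: str
    confidence: float
    bilateral_suspect: bool
    slices_grown: list[int] = field(default_factory=list)


def _head_mask(data):
    # brain-extracted input: background ~ 0; threshold well below tissue
    peak = np.percentile(data, 99.5)
    if peak <= 0:
        return np.zeros(data.shape, dtype=bool)
    return data > 0.1 * peak


def _rotate_inplane(arr, angle_deg, order):
    if angle_deg == 0:
        return arr.copy()
    return ndimage.rotate(arr, angle_deg, axes=(0, 1), reshape=False, order=order,
                          mode="constant", cval=0.0, prefilter=order > 1)


def _mirror_dice_scores(mask2d, candidates):
    """Dice of a 2D mask with its reflection about each candidate column."""
    nx = mask2d.shape[0]
    flipped = mask2d[::-1]  # flipped[x] = mask2d[nx-1-x]
    total = 2.0 * mask2d.sum()
    scores = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        # reflection about column c: R[x] = mask2d[2c - x] = flipped[x + nx-1-2c]
        shift = nx - 1 - 2 * c
        if shift >= 0:
            inter = (mask2d[: nx - shift] & flipped[shift:]).sum()
        else:
            inter = (mask2d[-shift:] & flipped[: nx + shift]).sum()
        scores[i] = 2.0 * inter / total if total else 0.0
    return scores


def align_vertical(vol: Volume3D) -> AlignmentResult:
    """Rotate the volume in-plane so the hemispheres split at one column.

    Exhaustive grid search: rotations in [-20, +20] degrees at 0.5-degree
    steps crossed with midline candidates in the central third of the
    x-range, scoring each pair by the Dice overlap of the (z-projected)
    head mask with its left-right reflection about the candidate column.
    Deterministic; ties resolve to the smallest angle, then column.
    """
    head = _head_mask(vol.data)
    if not head.any():
        raise ValueError("empty volume: no in-brain voxels found")
    proj = head.any(axis=2)
    xs = np.flatnonzero(proj.any(axis=1))
    nx = vol.shape[0]
    if xs[0] == 0 and xs[-1] == nx - 1:
        raise ValueError("head mask touches both x-extremes; cannot bracket a midline")
    candidates = np.arange(nx // 3, nx - nx // 3)
    if len(candidates) == 0:
        raise ValueError(f"x-dimension {nx} too small to search a midline")

    angles = np.arange(-ROTATION_RANGE_DEG, ROTATION_RANGE_DEG + 1e-9, ROTATION_STEP_DEG)
    angles = np.round(angles, 6)
    # prefer the smallest correction: ties resolve to the smallest |angle|
    angles = sorted(angles, key=lambda a: (abs(a), a))
    best = (-1.0, 0.0, int(candidates[0]))
    for ang in angles:
        rot_proj = _rotate_inplane(proj.astype(np.uint8), ang, order=0).astype(bool)
        if not rot_proj.any():
            continue
        scores = _mirror_dice_scores(rot_proj, candidates)
        j = int(np.argmax(scores))
        if scores[j] > best[0] + 1e-12:
            best = (float(scores[j]), float(ang), int(candidates[j]))
    score, angle, midline = best
    if score < 0:
        raise ValueError("alignment search failed on empty projections")
    aligned_data = _rotate_inplane(vol.data, angle, order=1)
    aligned = Volume3D(data=np.clip(aligned_data, 0, None), spacing=vol.spacing,
                       slice_gap=vol.slice_gap, affine=vol.affine)
    return AlignmentResult(rotation_deg=angle, midline_x=midline, aligned=aligned, score=score)


def split_hemispheres(res: AlignmentResult):
    """Cut the aligned volume at the midline column (the column itself excluded).

    left ∪ midline column ∪ right tiles the aligned volume exactly.
    """
    vol = res.aligned
    mid = res.midline_x
    nx = vol.shape[0]
    if mid <= 0 or mid >= nx - 1:
        raise ValueError(f"midline {mid} at volume edge")
    mk = lambda d: Volume3D(data=d, spacing=vol.spacing, slice_gap=vol.slice_gap)
    return mk(vol.data[:mid]), mk(vol.data[mid + 1:])


def _mirror_right(right_data, width):
    """Mirror the right hemisphere into left-hemisphere coordinates.

    With the midline column excluded, left column x pairs with the full
    volume column 2*mid - x, i.e. right-array index mid-1-x (mid = left
    width). The mirrored array is the reversed right hemisphere, right-
    aligned to the left width and zero-padded where no partner exists.
    """
    flipped = right_data[::-1]
    nr = flipped.shape[0]
    if nr < width:
        return np.pad(flipped, [(width - nr, 0), (0, 0), (0, 0)])
    return flipped[nr - width:]


def _erode_inplane(mask, iterations):
    if iterations <= 0 or not mask.any():
        return mask
    struct = np.zeros((3, 3, 1), dtype=bool)
    struct[1, :, 0] = True
    struct[:, 1, 0] = True
    return ndimage.binary_erosion(mask, structure=struct, iterations=iterations,
                                  border_value=0)


def asymmetry_map(left: Volume3D, right: Volume3D, params: RGParams | None = None,
                  midline_x: int | None = None, full_shape=None) -> AsymmetryResult:
    """Locate the tumor side by mirrored hemisphere subtraction.

    The difference |left - mirror(right)| is thresholded at
    ``asymmetry_threshold`` times a robust noise scale (1.4826 x the median
    absolute signed difference over in-brain voxels), within the in-plane-
    eroded brain mask (the head rim is excluded: sub-voxel alignment
    residuals show up there as spurious differences). Supra-threshold
    voxels are attributed to the hemisphere that is *brighter* at that
    location; the side holding the larger share of supra-threshold mass is
    the tumor side and that share is the confidence (0.5 when there is no
    mass — the symmetric / bilateral-mirrored case).
    """
    params = params or RGParams()
    nl, nr = left.shape[0], right.shape[0]
    L = left.data
    mirR = _mirror_right(right.data, nl)
    if L.shape != mirR.shape:
        raise ValueError(f"hemisphere shapes differ after mirroring: {L.shape} vs {mirR.shape}")
    signed = L - mirR
    diff = np.abs(signed)
    brain = (L > 0) | (mirR > 0)
    if brain.any():
        sigma = MAD_SCALE * float(np.median(np.abs(signed[brain])))
    else:
        sigma = 0.0
    thr = params.asymmetry_threshold * sigma
    core_brain = _erode_inplane(brain, params.rim_exclusion)
    supra = (diff > thr) & core_brain
    mass_left = float(diff[supra & (signed > 0)].sum())
    mass_right = float(diff[supra & (signed < 0)].sum())
    total = mass_left + mass_right
    if total == 0:
        side, confidence = "left", 0.5
        cand_hemi = np.zeros_like(supra)
    elif mass_left >= mass_right:
        side, confidence = "left", mass_left / total
        cand_hemi = supra & (signed > 0)
    else:
        side, confidence = "right", mass_right / total
        cand_hemi = supra & (signed < 0)

    # embed the candidate region into full aligned-volume coordinates
    mid = nl if midline_x is None else midline_x
    if full_shape is None:
        full_shape = (nl + nr + 1,) + left.shape[1:]
    candidate = np.zeros(full_shape, dtype=bool)
    if side == "left":
        candidate[:nl] = cand_hemi
    else:
        # left index x pairs with full column 2*mid - x
        k0 = max(0, nl - nr)
        count = nl - k0
        candidate[mid + 1: mid + 1 + count] = cand_hemi[k0:nl][::-1]
    return AsymmetryResult(diff_left=diff, diff_right=diff.copy(), tumor_side=side,
                           candidate_region=candidate, confidence=confidence,
                           noise_sigma=sigma)


def contrast_stretch(slice_img: np.ndarray, params: RGParams | None = None) -> np.ndarray:
    """Percentile-linear rescale of a slice to [0, 1].

    The p_low / p_high percentiles of in-brain (positive) intensities map to
    0 and 1; values outside are clipped. Monotone non-decreasing. A constant
    slice is returned as all zeros with a warning.
    """
    params = params or RGParams()
    img = np.asarray(slice_img, dtype=np.float64)
    inbrain = img[img > 0]
    src = inbrain if inbrain.size else img.ravel()
    lo, hi = np.percentile(src, params.stretch_percentiles)
    if hi - lo <= 0:
        logger.warning("contrast_stretch: constant slice (value %g); returning zeros", lo)
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def select_seed(slice_img: np.ndarray, candidate_region_slice: np.ndarray):
    """Brightest voxel inside the candidate region; lexicographic tie-break.

    Returns None when the candidate region is empty on this slice (the slice
    is skipped, not an error).
    """
    region = np.asarray(candidate_region_slice, dtype=bool)
    if not region.any():
        return None
    vals = np.where(region, slice_img, -np.inf)
    peak = vals.max()
    coords = np.argwhere(vals == peak)
    r, c = min(map(tuple, coords))
    return (int(r), int(c))


def _structure(connectivity):
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def region_grow(slice_img: np.ndarray, seed, params: RGParams | None = None) -> np.ndarray:
    """Grow the connected region of voxels intensity-similar to the seed.

    A voxel belongs iff |intensity - seed intensity| <= intensity_tolerance
    and it is connected to the seed (4- or 8-connectivity). The returned
    mask is the single connected component containing the seed.
    """
    params = params or RGParams()
    img = np.asarray(slice_img, dtype=np.float64)
    r, c = seed
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed {seed} outside image bounds {img.shape}")
    similar = np.abs(img - img[r, c]) <= params.intensity_tolerance
    lab, _ = ndimage.label(similar, structure=_structure(params.connectivity))
    return lab == lab[r, c]


def segment_rg(vol: Volume3D, params: RGParams | None = None):
    """Whole-tumor segmentation by hemisphere symmetry + region growing.

    Returns ``(mask, diagnostics)``. The mask stores the whole tumor as
    label 2 with ``undifferentiated=True`` — the method cannot split the
    tumor into edema and necrotic components. When the asymmetry mass is
    split nearly evenly between hemispheres the diagnostics carry
    ``bilateral_suspect=True``: the one-hemisphere assumption is violated
    and the output is not trustworthy.
    """
    params = params or RGParams()
    res = align_vertical(vol)
    left, right = split_hemispheres(res)
    asym = asymmetry_map(left, right, params, midline_x=res.midline_x,
                         full_shape=res.aligned.shape)
    bilateral = asym.confidence < params.bilateral_confidence_floor
    if bilateral:
        logger.warning(
            "bilateral-suspect: asymmetry confidence %.3f < %.3f; the one-hemisphere "
            "assumption appears violated", asym.confidence, params.bilateral_confidence_floor)

    grown = np.zeros(res.aligned.shape, dtype=bool)
    slices_grown = []
    struct2d = _structure(params.connectivity)
    for z in range(res.aligned.shape[2]):
        cand = asym.candidate_region[:, :, z]
        if cand.any() and params.candidate_min_area > 1:
            lab, n = ndimage.label(cand, structure=struct2d)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            cand = (sizes >= params.candidate_min_area)[lab] & cand
        if not cand.any():
            continue
        stretched = contrast_stretch(res.aligned.data[:, :, z], params)
        seed = select_seed(stretched, cand)
        if seed is None:
            continue
        mask2d = region_grow(stretched, seed, params)
        if params.fill_holes:
            mask2d = ndimage.binary_fill_holes(mask2d)
        grown[:, :, z] = mask2d
        slices_grown.append(z)
    if not slices_grown:
        logger.warning("segment_rg: no slices grown; returning empty mask")

    # map back through the inverse alignment (nearest neighbor keeps it binary)
    if res.rotation_deg != 0:
        back = _rotate_inplane(grown.astype(np.uint8), -res.rotation_deg, order=0).astype(bool)
    else:
        back = grown
    labels = np.where(back, LABEL_EDEMA, 0).astype(np.int16)
    mask = LabelMask(labels=labels, spacing=vol.spacing, slice_gap=vol.slice_gap,
                     affine=vol.affine, undifferentiated=True)
    diag = RGDiagnostics(rotation_deg=res.rotation_deg, midline_x=res.midline_x,
                         tumor_side=asym.tumor_side, confidence=asym.confidence,
                         bilateral_suspect=bilateral, slices_grown=slices_grown)
    return mask, diag
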