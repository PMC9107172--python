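"""Segmentation performance metrics: Dice, boundary Hausdorff distance, volume.

Conventions (logged in every report):

- Dice = 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty, 0.0 when
  exactly one is.
- Hausdorff distance is the plain (100th percentile) symmetric max-min
  distance between *boundary* voxels — foreground voxels with at least one
  face-adjacent background or out-of-volume neighbor. Euclidean in voxel
  units by default; in mm when spacing is supplied, with the slice gap
  folded into the effective z step (boundary positions are physical).
  Undefined when either mask is empty.
- Volume is the voxel count; mm^3 uses dx*dy*dz with the slice *thickness*
  only — the gap between slices was never imaged, so it is reported as a
  caveat rather than silently folded into the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_nifti import LabelMask

__all__ = [
    "dice",
    "boundary_voxels",
    "hausdorff",
    "volume",
    "evaluate",
    "batch_report",
    "ComponentMetrics",
    "MetricsReport",
    "COMPONENTS",
]

COMPONENTS = ("whole_tumor", "edema", "necrotic")


def _as_bool(mask):
    return np.asarray(mask, dtype=bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) in [0, 1]."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_voxels(mask) -> np.ndarray:
    """Boolean mask of foreground voxels with a face-adjacent background
    (or out-of-volume) neighbor; 6-connectivity in 3D, 4-connectivity in 2D."""
    m = _as_bool(mask)
    if not m.any():
        return np.zeros_like(m)
    struct = ndimage.generate_binary_structure(m.ndim, 1)
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~interior


def hausdorff(a, b, spacing=None) -> float:
    """Symmetric Hausdorff distance between the boundary voxel sets of two masks.

    max( sup_{a∈∂A} inf_{b∈∂B} d(a,b), sup_{b∈∂B} inf_{a∈∂A} d(a,b) ).
    Distances are Euclidean in voxel units, or in mm when ``spacing`` is
    given (pass the effective spacing, slice gap included, for
    non-contiguous acquisitions). Raises on an empty mask: record the value
    as "undefined" in reports.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff undefined for an empty mask; record 'undefined'")
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    sampling = None if spacing is None else tuple(spacing)
    # exact EDT: distance from every voxel to the nearest boundary voxel
    d_to_b = ndimage.distance_transform_edt(~bb, sampling=sampling)
    d_to_a = ndimage.distance_transform_edt(~ba, sampling=sampling)
    return float(max(d_to_b[ba].max(), d_to_a[bb].max()))


def volume(mask, spacing=None, slice_gap=None):
    """(voxel count, mm^3 or None). mm^3 = count * dx * dy * dz (thickness).

    The slice gap never enters the product — voxels in the gap were not
    imaged — but callers should surface it as a caveat when nonzero.
    """
    n = int(_as_bool(mask).sum())
    if spacing is None:
        return n, None
    dx, dy, dz = spacing
    return n, n * dx * dy * dz


@dataclass
class ComponentMetrics:
    component: str
    produced: bool = True
    dsc: float | None = None
    hausdorff_voxels: float | None = None
    hausdorff_mm: float | None = None
    hausdorff_undefined: bool = False
    vol_pred_voxels: int = 0
    vol_gt_voxels: int = 0
    vol_pred_mm3: float | None = None
    vol_gt_mm3: float | None = None

    def as_row(self, case=""):
        return {
            "case": case,
            "component": self.component,
            "dsc": self.dsc if self.produced else None,
            "hausdorff_voxels": self.hausdorff_voxels,
            "hausdorff_mm": self.hausdorff_mm,
            "vol_pred_voxels": self.vol_pred_voxels if self.produced else None,
            "vol_gt_voxels": self.vol_gt_voxels,
            "vol_pred_mm3": self.vol_pred_mm3 if self.produced else None,
            "vol_gt_mm3": self.vol_gt_mm3,
            "flags": "not produced" if not self.produced
                     else ("hausdorff undefined" if self.hausdorff_undefined else ""),
        }


@dataclass
class MetricsReport:
    """Per-component metrics for one prediction/ground-truth pair."""

    components: dict[str, ComponentMetrics] = field(default_factory=dict)
    slice_gap: float = 0.0
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, key):
        return self.components[key]

    def to_frame(self, case=""):
        return pd.DataFrame([cm.as_row(case) for cm in self.components.values()])


def _component_masks(mask: LabelMask):
    return {
        "whole_tumor": mask.whole_tumor(),
        "edema": mask.edema(),
        "necrotic": mask.necrotic(),
    }


def evaluate(pred: LabelMask, gt: LabelMask) -> MetricsReport:
    """All three metrics for whole tumor, edema and necrotic components.

    Components the predicting method does not output (a whole-tumor-only
    method such as symmetry region growing, marked ``undifferentiated``)
    are reported as not produced — the dash cells of a comparison table —
    rather than as zero-overlap failures.
    """
    from .io_nifti import check_geometry_compatible

    geo = check_geometry_compatible(pred, gt)
    if not geo.compatible:
        raise ValueError("geometry mismatch: " + "; ".join(geo.mismatches))
    spacing = gt.spacing
    eff = (spacing[0], spacing[1], spacing[2] + gt.slice_gap)
    pm, gm = _component_masks(pred), _component_masks(gt)
    report = MetricsReport(slice_gap=gt.slice_gap)
    report.notes.append("dice=1.0 for two empty masks; hausdorff undefined for any empty mask")
    if gt.slice_gap > 0:
        report.notes.append(
            f"slice gap {gt.slice_gap} mm excluded from mm^3 volumes (unimaged)")
    for comp in COMPONENTS:
        produced = not (pred.undifferentiated and comp in ("edema", "necrotic"))
        p, g = pm[comp], gm[comp]
        nv_g, mm3_g = volume(g, spacing)
        cm = ComponentMetrics(component=comp, produced=produced,
                              vol_gt_voxels=nv_g, vol_gt_mm3=mm3_g)
        if produced:
            cm.dsc = dice(p, g)
            cm.vol_pred_voxels, cm.vol_pred_mm3 = volume(p, spacing)
            try:
                cm.hausdorff_voxels = hausdorff(p, g)
                cm.hausdorff_mm = hausdorff(p, g, spacing=eff)
            except ValueError:
                cm.hausdorff_undefined = True
        report.components[comp] = cm
    return report


def batch_report(cases) -> pd.DataFrame:
    """Aggregate per-case metrics plus per-component means.

    ``cases`` is a sequence of (name, pred, gt) or (pred, gt) tuples.
    Undefined Hausdorff entries are excluded from that metric's mean; the
    mean rows carry the excluded count.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("batch_report needs at least one case")
    rows = []
    for i, case in enumerate(cases):
        if len(case) == 3:
            name, pred, gt = case
        else:
            pred, gt = case
            name = f"case{i}"
        rep = evaluate(pred, gt)
        rows.extend(cm.as_row(name) for cm in rep.components.values())
    table = pd.DataFrame(rows)
    means = []
    for comp in COMPONENTS:
        sub = table[table.component == comp]
        hd = sub["hausdorff_voxels"].dropna()
        produced = sub["dsc"].dropna()
        excluded = int(len(sub[sub["flags"] != "not produced"]) - len(hd))
        means.append({
            "case": "MEAN",
            "component": comp,
            "dsc": produced.mean() if len(produced) else None,
            "hausdorff_voxels": hd.mean() if len(hd) else None,
            "hausdorff_mm": sub["hausdorff_mm"].dropna().mean() if len(hd) else None,
            "vol_pred_voxels": sub["vol_pred_voxels"].dropna().mean() if len(produced) else None,
            "vol_gt_voxels": sub["vol_gt_voxels"].mean(),
            "vol_pred_mm3": sub["vol_pred_mm3"].dropna().mean() if len(produced) else None,
            "vol_gt_mm3": sub["vol_gt_mm3"].mean(),
            "flags": f"hausdorff excluded: {excluded}" if excluded else "",
        })
    return pd.DataFrame(rows + means)
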