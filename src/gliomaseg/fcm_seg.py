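"""Fuzzy C-means tumor segmentation with component labeling.

Classical FCM minimizes the cost

    J = sum_j sum_i w_ij^m ||x_j - c_i||^2

by alternating the centroid update c_i = sum_j w_ij^m x_j / sum_j w_ij^m and
the membership update w_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)), where d_ij is
the absolute intensity difference between data point j and centroid i. Each
point holds a graded membership to every cluster (rows sum to 1); m > 1
controls the fuzziness of the partition.

Segmentation is slice-wise on intensity alone: every axial slice is clustered
independently, the brightest cluster becomes edema (on FLAIR edema is
hyperintense), and the cluster immediately below it is relabeled necrotic
where its voxels fall inside the filled convex hull of the edema component
(the non-enhancing core sits geometrically inside the edema shell). Small
connected components are then removed — the equivalent of MATLAB's
``bwareaopen`` cleanup — to drop isolated misclassified voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import convex_hull_image, remove_small_objects

from .io_nifti import LABEL_EDEMA, LABEL_NECROTIC, LabelMask, Volume3D

__all__ = [
    "FCMParams",
    "FCMState",
    "fcm_cluster",
    "fcm_cost",
    "assign_components",
    "remove_small_objects_mask",
    "segment_fcm",
]

logger = logging.getLogger(__name__)

#: two centroids closer than this fraction of the centroid range are merged
#: into one intensity level when mapping clusters to tissues
MERGE_FRACTION = 1e-3
#: the top cluster counts as tumor only if it is separated from the next
#: level by at least this fraction of the centroid range (guards slices
#: without tumor, where the top clusters merely split the normal-brain mode)
MIN_TOP_GAP_FRACTION = 0.15


@dataclass
class FCMParams:
    """Fuzzy C-means parameters.

    C: number of clusters (default 4: background-ish, normal brain,
       necrotic, edema). m: fuzziness exponent (> 1; 2 is the classical
       choice). tol: convergence threshold on the max centroid change, in
       intensity units. min_area: minimum in-plane connected-component area
       (voxels) kept by the cleanup step. seed only matters for the optional
       random-restart mode; the default initialization is deterministic.
    """

    C: int = 4
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    seed: int = 0
    min_area: int = 20
    connectivity: int = 8
    mode: str = "components"  # "components" (labels 1+2) or "whole" (label 2 only)

    def __post_init__(self):
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.mode not in ("components", "whole"):
            raise ValueError("mode must be 'components' or 'whole'")


@dataclass
class FCMState:
    """Converged (or iteration-capped) FCM state.

    centroids are sorted ascending; memberships is (C, N) with columns
    summing to 1; cost is the final value of J.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    cost_history: list[float] = field(default_factory=list)
    empty_clusters: list[int] = field(default_factory=list)


def fcm_cost(values, memberships, centroids, m) -> float:
    """The FCM cost J = sum_j sum_i w_ij^m (x_j - c_i)^2, exactly as defined."""
    x = np.asarray(values, dtype=np.float64).ravel()
    w = np.asarray(memberships, dtype=np.float64)
    c = np.asarray(centroids, dtype=np.float64).ravel()
    if w.shape != (c.size, x.size):
        raise ValueError(f"memberships shape {w.shape} != (C={c.size}, N={x.size})")
    d2 = (x[None, :] - c[:, None]) ** 2
    return float(((w ** m) * d2).sum())


def _memberships(x, c, m):
    """Standard FCM membership update; exact (0/1) at zero distances."""
    d = np.abs(x[None, :] - c[:, None])  # (C, N)
    zero = d < 1e-300
    w = np.empty_like(d)
    expo = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-expo)
        w = inv / inv.sum(axis=0)
    coincident = zero.any(axis=0)
    if coincident.any():
        w[:, coincident] = zero[:, coincident] / zero[:, coincident].sum(axis=0)
    return w


def fcm_cluster(values, params: FCMParams | None = None,
                init_centroids=None) -> FCMState:
    """Cluster 1D intensities by fuzzy C-means.

    Deterministic: centroids start evenly spaced over the robust (1st-99th
    percentile) intensity range unless ``init_centroids`` is given. Stops
    when the largest centroid move falls below ``tol`` or at ``max_iter``.
    Returns centroids sorted ascending with memberships permuted to match.
    """
    params = params or FCMParams()
    x = np.asarray(values, dtype=np.float64).ravel()
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    N, C, m = x.size, params.C, params.m
    if N < C:
        raise ValueError(f"need at least C={C} data points, got {N}")

    if np.ptp(x) == 0:
        if C == 1:
            w = np.ones((1, N))
            return FCMState(centroids=np.array([x[0]]), memberships=w,
                            cost=0.0, n_iter=0, converged=True, cost_history=[0.0])
        # degenerate: all values identical with C >= 2
        c = np.full(C, x[0])
        w = np.full((C, N), 1.0 / C)
        return FCMState(centroids=c, memberships=w, cost=0.0, n_iter=0,
                        converged=False, cost_history=[0.0],
                        empty_clusters=list(range(1, C)))

    if init_centroids is not None:
        c = np.asarray(init_centroids, dtype=np.float64).copy()
        if c.size != C:
            raise ValueError("init_centroids length must equal C")
    else:
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = x.min(), x.max()
        c = lo + (hi - lo) * (2 * np.arange(C) + 1) / (2 * C)

    w = _memberships(x, c, m)
    history = [fcm_cost(x, w, c, m)]
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        wm = w ** m
        denom = wm.sum(axis=1)
        mass = denom > 0
        c_new = c.copy()
        c_new[mass] = (wm[mass] @ x) / denom[mass]
        delta = np.max(np.abs(c_new - c))
        c = c_new
        w = _memberships(x, c, m)
        history.append(fcm_cost(x, w, c, m))
        if delta < params.tol:
            converged = True
            break

    order = np.argsort(c, kind="stable")
    c, w = c[order], w[order]
    hard = np.argmax(w, axis=0)
    empty = [i for i in range(C) if not (hard == i).any()]
    return FCMState(centroids=c, memberships=w, cost=history[-1], n_iter=it,
                    converged=converged, cost_history=history, empty_clusters=empty)


def _merged_levels(centroids):
    """Collapse near-coincident centroids into distinct intensity levels.

    Returns (levels, level_of_cluster) where levels are ascending distinct
    centroid intensities and level_of_cluster maps each cluster index to its
    level index.
    """
    c = np.asarray(centroids, dtype=np.float64)
    rng = float(c.max() - c.min())
    tol = MERGE_FRACTION * rng if rng > 0 else 0.0
    levels = [c[0]]
    level_of = [0]
    for ci in c[1:]:
        if ci - levels[-1] <= tol:
            level_of.append(len(levels) - 1)
        else:
            levels.append(ci)
            level_of.append(len(levels) - 1)
    return np.asarray(levels), np.asarray(level_of)


def assign_components(slice_img, state: FCMState, in_brain_mask=None,
                      mode: str = "components", min_area: int = 0,
                      connectivity: int = 8) -> np.ndarray:
    """Map clusters to tissue labels on one slice.

    Voxels are hard-assigned to their nearest centroid (for scalar FCM the
    maximum-membership cluster; ties go to the higher centroid). With
    centroids sorted ascending the top intensity level becomes edema
    (label 2); the level immediately below is relabeled necrotic (label 1)
    where its voxels lie inside the filled convex hull of the edema
    component. In "whole" mode only the top level is emitted, as label 2.

    The top level only counts as tumor when it is separated from the level
    below by a minimum fraction of the centroid range — on tumor-free slices
    the top clusters merely subdivide normal brain and are rejected.
    """
    img = np.asarray(slice_img, dtype=np.float64)
    mask = np.ones(img.shape, bool) if in_brain_mask is None else np.asarray(in_brain_mask, bool)
    out = np.zeros(img.shape, dtype=np.int16)
    c = state.centroids
    if mode == "components" and c.size < 3:
        raise ValueError("component labeling needs C >= 3 (use mode='whole' for C = 2)")
    if mode == "whole" and c.size < 2:
        raise ValueError("whole-tumor mode needs C >= 2")
    levels, _ = _merged_levels(c)
    if levels.size < 2:
        return out
    rng = levels[-1] - levels[0]
    if levels[-1] - levels[-2] < MIN_TOP_GAP_FRACTION * rng:
        return out
    if mode == "components" and levels.size < 3:
        return out

    # nearest-level hard assignment; ties at midpoints go to the higher level
    edges = (levels[:-1] + levels[1:]) / 2.0
    assigned = np.searchsorted(edges, img, side="right")
    top = levels.size - 1
    edema = mask & (assigned == top)
    if mode == "components":
        # tumor is a minority tissue: if the top level holds most of the
        # non-background mass the clusters merely split normal brain
        nonbottom = mask & (assigned > 0)
        if edema.sum() * 2 >= max(int(nonbottom.sum()), 1):
            return out
    if min_area:
        # scattered misclassified voxels would inflate the convex hull below
        edema = remove_small_objects_mask(edema, min_area, connectivity)
    out[edema] = LABEL_EDEMA
    if mode == "whole":
        return out
    if edema.any():
        hull = convex_hull_image(edema)
        necrotic = mask & (assigned == top - 1) & hull
        out[necrotic] = LABEL_NECROTIC
    return out


def remove_small_objects_mask(mask, min_area, connectivity=8) -> np.ndarray:
    """Delete connected components smaller than ``min_area`` voxels.

    The 2D area-opening step of the pipeline (MATLAB ``bwareaopen``);
    components of at least min_area voxels pass through untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 0:
        return mask.copy()
    conn = 1 if connectivity == 4 else mask.ndim
    # max_size semantics: removes components of size <= max_size, i.e. < min_area
    return remove_small_objects(mask, max_size=min_area - 1, connectivity=conn)


def segment_fcm(vol: Volume3D, params: FCMParams | None = None) -> LabelMask:
    """Slice-wise FCM tumor segmentation of a single-modality volume.

    Each axial slice is clustered independently over all its voxels,
    clusters are mapped to tissue labels, and each label is cleaned by
    small-object removal. Slices with fewer voxels than C or with no
    intensity spread are skipped with a log entry. Deterministic.
    """
    params = params or FCMParams()
    labels = np.zeros(vol.shape, dtype=np.int16)
    for z in range(vol.shape[2]):
        img = vol.data[:, :, z]
        x = img.ravel()
        if x.size < params.C or np.ptp(x) == 0:
            logger.info("segment_fcm: skipping slice %d (too few voxels or constant)", z)
            continue
        state = fcm_cluster(x, params)
        sl = assign_components(img, state, mode=params.mode,
                               min_area=params.min_area, connectivity=params.connectivity)
        for lab in (LABEL_NECROTIC, LABEL_EDEMA):
            m = sl == lab
            if m.any():
                kept = remove_small_objects_mask(m, params.min_area, params.connectivity)
                sl[m & ~kept] = 0
        labels[:, :, z] = sl
    return LabelMask(labels=labels, spacing=vol.spacing, slice_gap=vol.slice_gap,
                     affine=vol.affine, undifferentiated=False)
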