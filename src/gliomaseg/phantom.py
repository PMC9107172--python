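"""Synthetic brain-like MRI phantoms with ground-truth tumor masks.

The phantom emulates a skull-stripped, bias-uncorrected FLAIR-like volume:
an ellipsoidal "head" of uniform brain tissue on an exactly-zero background
(as a brain-extraction tool would leave it), containing a tumor built from
two concentric ellipsoids — a necrotic core (label 1) inside an edema shell
(label 2), both brighter than brain, with edema brightest (the FLAIR
ordering). Optional corruptions: a smooth multiplicative bias field
(product of per-axis inverted parabolas), additive Gaussian noise confined
to the head, and an in-plane rotation of the whole volume.

Two geometry presets mirror the acquisition styles the algorithms must
handle: isotropic 1 mm benchmark-style volumes, and anisotropic
clinical-style stacks (0.5 mm in-plane, 5 mm slices with a 1.5 mm gap,
scaled-down in-plane matrix for desk-scale speed).

The head is centered on an integer voxel column so a left-tumor phantom and
its right-tumor counterpart are exact left-right array flips of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_nifti import LABEL_EDEMA, LABEL_NECROTIC, LabelMask, Volume3D

__all__ = ["PhantomSpec", "make_phantom", "make_clinical_phantom", "phantom_suite",
           "SUITE_CASES", "DEFAULT_TISSUES"]

DEFAULT_TISSUES = {"background": 0.0, "brain": 40.0, "necrotic": 60.0, "edema": 90.0}

SUITE_CASES = ("symmetric_clean", "unilateral_LGG_like", "unilateral_HGG_like",
               "bilateral_mirrored", "rotated_7deg", "noisy_biased")


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom deterministically.

    Radii are in-plane voxel radii; the through-plane semi-axis is derived
    from the voxel anisotropy (r * dx / (dz + gap)) so tumors stay roughly
    spherical in physical space on anisotropic grids. ``tumor_center=None``
    places the tumor automatically from ``laterality``.
    """

    shape: tuple[int, int, int] = (128, 112, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_gap: float = 0.0
    head_axes: tuple[float, float, float] | None = None  # voxel semi-axes
    tissue_intensities: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    tumor: bool = True
    tumor_center: tuple[int, int, int] | None = None
    core_radius: float = 10.0
    edema_radius: float = 24.0
    laterality: str = "left"  # left | right | bilateral_mirrored | midline
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.tumor and not self.edema_radius > self.core_radius > 0:
            raise ValueError("need edema_radius > core_radius > 0")
        t = self.tissue_intensities
        if not t["background"] < t["brain"] < t["necrotic"] < t["edema"]:
            raise ValueError("tissue intensities must be ordered background < brain < necrotic < edema")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.laterality not in ("left", "right", "bilateral_mirrored", "midline"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.head_axes is None:
            nx, ny, nz = self.shape
            self.head_axes = (0.42 * nx, 0.42 * ny, 0.44 * nz)


def _ellipsoid(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _tumor_semi_axes(spec, radius):
    # keep the tumor physically round: scale the y/z semi-axes by anisotropy
    dx, dy, dz = spec.spacing
    rz = max(1.0, radius * dx / (dz + spec.slice_gap))
    return (radius, radius * dx / dy, rz)


def _bias_field(shape, amplitude):
    if amplitude == 0:
        return None
    axes = []
    for n in shape:
        u = np.linspace(-1.0, 1.0, n)
        axes.append(1.0 - u ** 2)
    B = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return 1.0 + amplitude * (2.0 * B - 1.0)


def make_phantom(spec: PhantomSpec):
    """Build (Volume3D, LabelMask) from a spec. Deterministic given the seed.

    Construction order: piecewise-constant tissues -> multiplicative bias ->
    additive Gaussian noise inside the head -> in-plane rotation -> left-right
    flip for right laterality. Raises if the tumor protrudes from the head.
    """
    nx, ny, nz = spec.shape
    cx = nx // 2  # integer midline column: exact mirror symmetry
    head_center = (cx, (ny - 1) / 2.0, (nz - 1) / 2.0)
    head = _ellipsoid(spec.shape, head_center, spec.head_axes)
    if not head.any():
        raise ValueError("degenerate head ellipsoid")

    t = spec.tissue_intensities
    data = np.where(head, t["brain"], t["background"]).astype(np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)

    if spec.tumor:
        if spec.tumor_center is None:
            off = 0.45 * spec.head_axes[0]
            center = (int(round(cx - off)), int(round(head_center[1])),
                      int(round(head_center[2])))
        else:
            center = tuple(spec.tumor_center)
            if spec.laterality == "right":
                center = (2 * cx - center[0], center[1], center[2])
        if spec.laterality == "midline":
            center = (cx, center[1], center[2])
        centers = [center]
        if spec.laterality == "bilateral_mirrored":
            centers.append((2 * cx - center[0], center[1], center[2]))
        for c in centers:
            edema = _ellipsoid(spec.shape, c, _tumor_semi_axes(spec, spec.edema_radius))
            core = _ellipsoid(spec.shape, c, _tumor_semi_axes(spec, spec.core_radius))
            if (edema & ~head).any():
                raise ValueError("tumor protrudes outside the head ellipsoid")
            labels[edema] = LABEL_EDEMA
            labels[core] = LABEL_NECROTIC
        data[labels == LABEL_EDEMA] = t["edema"]
        data[labels == LABEL_NECROTIC] = t["necrotic"]

    bias = _bias_field(spec.shape, spec.bias_amplitude)
    if bias is not None:
        data = data * bias
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        data = data + np.where(head, noise, 0.0)
        np.clip(data, 0.0, None, out=data)

    if spec.rotation_deg != 0:
        data = ndimage.rotate(data, spec.rotation_deg, axes=(0, 1), reshape=False,
                              order=1, mode="constant", cval=0.0, prefilter=False)
        np.clip(data, 0.0, None, out=data)
        labels = ndimage.rotate(labels, spec.rotation_deg, axes=(0, 1),
                                reshape=False, order=0, mode="constant", cval=0)

    if spec.laterality == "right":
        data = data[::-1].copy()
        labels = labels[::-1].copy()

    vol = Volume3D(data=data, spacing=spec.spacing, slice_gap=spec.slice_gap)
    mask = LabelMask(labels=labels, spacing=spec.spacing, slice_gap=spec.slice_gap)
    return vol, mask


def make_clinical_phantom(**overrides):
    """Clinical-style anisotropic preset: 0.5 mm in-plane, 5 mm slices with a
    1.5 mm gap, 256x224x20 matrix (in-plane scaled down from 512x448), tumor
    radii sized for the finer in-plane grid."""
    return make_phantom(clinical_spec(**overrides))


def clinical_spec(scale: float = 1.0, **overrides) -> PhantomSpec:
    """The clinical-preset spec, optionally scaled in-plane (z stays fixed)."""
    nx, ny = int(round(256 * scale)), int(round(224 * scale))
    kw = dict(shape=(nx, ny, 20), spacing=(0.5, 0.5, 5.0), slice_gap=1.5,
              core_radius=12.0 * scale, edema_radius=36.0 * scale)
    kw.update(overrides)
    return PhantomSpec(**kw)


def phantom_suite(seed: int = 0, scale: float = 1.0) -> dict:
    """The canonical named fixtures, all on the clinical-style geometry.

    symmetric_clean       tumor-free, noise-free (the symmetry fixed point)
    unilateral_LGG_like   left tumor, large edema / small core, moderate noise
    unilateral_HGG_like   left tumor, large core, moderate noise
    bilateral_mirrored    identical mirrored tumors (the region-growing blind spot)
    rotated_7deg          LGG-like tumor with a +7 degree in-plane rotation
    noisy_biased          LGG-like tumor, heavier noise plus a bias field

    Returns {name: (Volume3D, LabelMask)}; deterministic given the seed.
    """
    mk = lambda i, **kw: make_phantom(clinical_spec(scale=scale, seed=int(seed) + i, **kw))
    lgg = dict(core_radius=10.0 * scale, edema_radius=36.0 * scale, noise_sigma=4.0)
    hgg = dict(core_radius=22.0 * scale, edema_radius=34.0 * scale, noise_sigma=4.0)
    return {
        "symmetric_clean": mk(0, tumor=False, noise_sigma=0.0),
        "unilateral_LGG_like": mk(1, **lgg),
        "unilateral_HGG_like": mk(2, **hgg),
        "bilateral_mirrored": mk(3, laterality="bilateral_mirrored", **lgg),
        "rotated_7deg": mk(4, rotation_deg=7.0, **lgg),
        "noisy_biased": mk(5, noise_sigma=6.0, bias_amplitude=0.1,
                           core_radius=10.0 * scale, edema_radius=36.0 * scale),
    }
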