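"""Synthetic per-subject contrast images with planted effects and smooth noise.

Stand-in for first-level GLM outputs: each subject's image is a shared mean
map (spherical activation "blobs" with amplitude expressed in Cohen's-d
units of the between-subject SD) plus an independent spatially smooth
Gaussian noise field.  Also implements the noise-injection perturbation used
by the robustness evaluation: additive white Gaussian noise whose SD is a
fraction (default 25%) of each image's mean absolute in-mask signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BrainMask, StatVolume, VolumeGrid

__all__ = [
    "ActivationBlob",
    "SyntheticSpec",
    "SubjectImageSet",
    "TruthMap",
    "default_grid",
    "make_mask",
    "generate_subject_images",
    "inject_noise",
    "spec_from_dict",
]

#: conversion between a Gaussian kernel's FWHM and its SD
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))

#: desk-scale default grid: 40 x 48 x 34 voxels at 2 mm (~65k voxels)
DEFAULT_SHAPE = (40, 48, 34)
DEFAULT_VOXEL_MM = 2.0
#: mm position of voxel (0,0,0): an MNI-like box spanning x -40..38,
#: y -40..54, z -24..42, so medial-frontal coordinates such as (-4, 48, 12)
#: fall inside the default ellipsoid mask
DEFAULT_ORIGIN_MM = (-40.0, -40.0, -24.0)


def default_grid() -> VolumeGrid:
    """Default desk-scale grid (MNI-like axis orientation and origin)."""
    return VolumeGrid.from_spacing(DEFAULT_SHAPE, (DEFAULT_VOXEL_MM,) * 3,
                                   DEFAULT_ORIGIN_MM)


@dataclass(frozen=True)
class ActivationBlob:
    """A spherical activated region: amplitude d_true in units of the
    between-subject SD (i.e. the true Cohen's d of the planted effect)."""

    center_voxel: tuple
    radius_voxels: float
    d_true: float

    def __post_init__(self):
        if self.radius_voxels <= 0:
            raise ValueError("radius_voxels must be positive")


@dataclass
class SyntheticSpec:
    """Generation recipe for one synthetic group dataset."""

    grid: VolumeGrid = field(default_factory=default_grid)
    n_subjects: int = 16
    sigma_between: float = 1.0
    smooth_fwhm_voxels: float = 3.0
    blobs: tuple = ()
    mask_shape: str = "ellipsoid"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (one-sample t needs df >= 1)")
        if self.sigma_between <= 0:
            raise ValueError("sigma_between must be positive")
        if self.smooth_fwhm_voxels < 0:
            raise ValueError("smooth_fwhm_voxels must be nonnegative")
        if self.mask_shape not in ("box", "ellipsoid"):
            raise ValueError("mask_shape must be 'box' or 'ellipsoid'")
        self.blobs = tuple(
            b if isinstance(b, ActivationBlob) else ActivationBlob(**b)
            for b in self.blobs
        )


@dataclass
class SubjectImageSet:
    """One contrast image per subject on a shared grid, plus the brain mask."""

    images: list
    mask: BrainMask

    def __post_init__(self):
        if len(self.images) < 2:
            raise ValueError("need at least 2 subject images")
        g = self.images[0].grid
        if any(im.grid != g for im in self.images) or self.mask.grid != g:
            raise ValueError("all images and the mask must share one grid")

    @property
    def n(self) -> int:
        return len(self.images)

    @property
    def grid(self) -> VolumeGrid:
        return self.images[0].grid

    def subset(self, indices) -> "SubjectImageSet":
        return SubjectImageSet([self.images[i] for i in indices], self.mask)

    def data_stack(self) -> np.ndarray:
        """(n, X, Y, Z) array of subject values."""
        return np.stack([im.values for im in self.images], axis=0)


@dataclass
class TruthMap:
    """Ground-truth activation (union of blob interiors); seed-invariant."""

    grid: VolumeGrid
    active: np.ndarray

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != self.grid.shape:
            raise ValueError("truth map shape does not match grid")


def make_mask(grid: VolumeGrid, mask_shape: str = "ellipsoid") -> BrainMask:
    """Box mask covering the grid, or the inscribed ellipsoid."""
    if mask_shape == "box":
        inside = np.ones(grid.shape, dtype=bool)
    elif mask_shape == "ellipsoid":
        centers = [(s - 1) / 2.0 for s in grid.shape]
        semi = [s / 2.0 for s in grid.shape]
        ax = [np.arange(s) for s in grid.shape]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        inside = (
            ((xx - centers[0]) / semi[0]) ** 2
            + ((yy - centers[1]) / semi[1]) ** 2
            + ((zz - centers[2]) / semi[2]) ** 2
        ) <= 1.0
    else:
        raise ValueError(f"unknown mask_shape {mask_shape!r}")
    return BrainMask(grid, inside)


def _blob_interior(grid: VolumeGrid, blob: ActivationBlob) -> np.ndarray:
    ax = [np.arange(s) for s in grid.shape]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    cx, cy, cz = blob.center_voxel
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
    return dist2 <= blob.radius_voxels**2


def truth_map(spec: SyntheticSpec, mask: BrainMask | None = None) -> TruthMap:
    """Union of blob interiors, clipped to the mask."""
    if mask is None:
        mask = make_mask(spec.grid, spec.mask_shape)
    active = np.zeros(spec.grid.shape, dtype=bool)
    for blob in spec.blobs:
        c = tuple(int(v) for v in blob.center_voxel)
        if not all(0 <= ci < s for ci, s in zip(c, spec.grid.shape)):
            raise ValueError(f"blob center {c} outside grid {spec.grid.shape}")
        if not mask.inside[c]:
            raise ValueError(f"blob center {c} outside the brain mask")
        active |= _blob_interior(spec.grid, blob)
    active &= mask.inside
    return TruthMap(spec.grid, active)


def _smooth_noise_field(rng: np.random.Generator, shape, fwhm_voxels: float,
                        mask: np.ndarray, sigma_between: float) -> np.ndarray:
    """White noise, optionally Gaussian-smoothed, rescaled so the in-mask SD
    equals sigma_between.  Rescaling happens after smoothing so that the
    smoothness knob does not change between-subject variance."""
    g = rng.standard_normal(shape)
    if fwhm_voxels > 0:
        g = ndimage.gaussian_filter(g, sigma=fwhm_voxels * FWHM_TO_SIGMA, mode="wrap")
    sd = g[mask].std()
    return g * (sigma_between / sd)


def generate_subject_images(spec: SyntheticSpec):
    """Generate per-subject contrast images: shared mean map + smooth noise.

    Returns ``(SubjectImageSet, TruthMap)``.  Deterministic given
    ``spec.seed``.
    """
    mask = make_mask(spec.grid, spec.mask_shape)
    truth = truth_map(spec, mask)

    mean_map = np.zeros(spec.grid.shape)
    for blob in spec.blobs:
        interior = _blob_interior(spec.grid, blob) & mask.inside
        mean_map[interior] = blob.d_true * spec.sigma_between

    rng = np.random.default_rng(spec.seed)
    images = []
    for _ in range(spec.n_subjects):
        noise = _smooth_noise_field(
            rng, spec.grid.shape, spec.smooth_fwhm_voxels, mask.inside,
            spec.sigma_between,
        )
        images.append(StatVolume(spec.grid, mean_map + noise, "contrast"))
    return SubjectImageSet(images, mask), truth


def inject_noise(images: SubjectImageSet, fraction: float, seed: int) -> SubjectImageSet:
    """Perturb each image with iid Gaussian noise scaled to its own signal.

    Per image, the noise SD is ``fraction`` times the mean absolute in-mask
    value ("mean signal strength" — contrast images are signed, so a plain
    mean could be ~0 and degenerate).  Out-of-mask voxels are untouched.
    Deterministic given ``seed``.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = images.mask.inside
    out = []
    for im in images.images:
        vals = im.values.copy()
        if fraction > 0:
            s = fraction * np.mean(np.abs(vals[mask]))
            if s > 0:
                vals[mask] += rng.normal(0.0, s, size=int(mask.sum()))
        out.append(StatVolume(im.grid, vals, im.kind))
    return SubjectImageSet(out, images.mask)


def spec_from_dict(cfg: dict) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a config mapping.

    Recognised keys: grid_shape, voxel_size_mm, n_subjects, sigma_between,
    smooth_fwhm_voxels, blobs (list of {center, radius, d_true}),
    mask_shape, seed.
    """
    shape = tuple(cfg.get("grid_shape", DEFAULT_SHAPE))
    vs = cfg.get("voxel_size_mm", DEFAULT_VOXEL_MM)
    if np.isscalar(vs):
        vs = (float(vs),) * 3
    origin = cfg.get("origin_mm")
    if origin is None:
        if shape == DEFAULT_SHAPE and tuple(vs) == (DEFAULT_VOXEL_MM,) * 3:
            origin = DEFAULT_ORIGIN_MM
        else:
            origin = -(np.asarray(shape) - 1) / 2.0 * np.asarray(vs)
    grid = VolumeGrid.from_spacing(shape, vs, origin)
    blobs = tuple(
        ActivationBlob(tuple(b["center"]), float(b["radius"]), float(b["d_true"]))
        for b in cfg.get("blobs", [])
    )
    return SyntheticSpec(
        grid=grid,
        n_subjects=int(cfg.get("n_subjects", 16)),
        sigma_between=float(cfg.get("sigma_between", 1.0)),
        smooth_fwhm_voxels=float(cfg.get("smooth_fwhm_voxels", 3.0)),
        blobs=blobs,
        mask_shape=cfg.get("mask_shape", "ellipsoid"),
        seed=int(cfg.get("seed", 0)),
    )
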