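"""Synthetic cerebral-vasculature phantoms and perturbed DRR training pairs.

No patient data is needed anywhere in the package: this module fabricates
(a) a vein mask of thick semicircular arcs hugging a skull-radius sphere —
the large dural sinuses that anchor the learned initialization, (b) an artery
mask of thinner bifurcating tubes interior to the sphere, (c) uniformly
sampled rigid pose perturbations, and (d) (fixed, moving, target) DRR pairs
in which the fixed image plays the role of a synthesized DSA at the
registered pose, the moving image is rendered after an extra random offset,
and the regression target is the offset's inverse.

Everything is deterministic given the seeds in the parameter dataclasses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import CArmGeometry, Projection2D, VolumeGrid
from .render import DrrRenderer, binarize
from .se3 import RigidTransform, compose, invert

__all__ = [
    "PhantomParams",
    "OffsetSamplerParams",
    "generate_vessel_phantom",
    "attenuation_volume",
    "sample_offset",
    "make_training_pair",
    "training_pairs",
    "make_dsa_frames",
    "smooth_blob_phantom",
    "DegeneratePairError",
]

log = logging.getLogger(__name__)

# binarization threshold for synthetic DRRs: any traversed vessel mass counts,
# emulating a binary DSA segmentation
DRR_BINARIZE_FRACTION = 1e-6


class DegeneratePairError(RuntimeError):
    """A training pair whose fixed or moving DRR is entirely empty."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the synthetic head.

    grid_size is voxels per axis; all physical sizes in mm.  The defaults
    give a 128 mm field of view holding a 50 mm 'skull' sphere, four thick
    vein arcs on its shell and a depth-3 arterial tree inside it.
    """

    grid_size: int = 64
    voxel_spacing: float = 2.0
    skull_radius: float = 50.0
    n_vein_arcs: int = 4
    vein_radius: float = 4.0
    n_artery_branches: int = 3
    artery_radius: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if min(self.skull_radius, self.vein_radius, self.artery_radius, self.voxel_spacing) <= 0:
            raise ValueError("all radii and spacings must be positive")
        if self.vein_radius <= self.artery_radius:
            raise ValueError("veins must be thicker than arteries")


@dataclass(frozen=True)
class OffsetSamplerParams:
    """Uniform per-axis pose perturbation ranges.

    Each rotation component is drawn uniformly in +-rotation_range[i] degrees,
    each translation component uniformly in +-translation_range[i] mm.  The
    ranges are anisotropic on purpose: real initial offsets are dominated by
    head 'slouch' about one axis, and the sampler should be able to express
    that.
    """

    rotation_range: tuple[float, float, float] = (15.0, 15.0, 15.0)
    translation_range: tuple[float, float, float] = (30.0, 30.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.rotation_range) or any(t < 0 for t in self.translation_range):
            raise ValueError("ranges must be non-negative")


def _stamp_tube(mask: np.ndarray, centers_vox: np.ndarray, radius_vox: float) -> bool:
    """Mark all voxels within radius of any center; returns True if clipped."""
    n = mask.shape[0]
    r = int(np.ceil(radius_vox))
    clipped = False
    offs = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    ball = (ox**2 + oy**2 + oz**2) <= radius_vox**2
    bx, by, bz = ox[ball], oy[ball], oz[ball]
    for c in np.round(centers_vox).astype(int):
        x, y, z = bx + c[0], by + c[1], bz + c[2]
        inside = (x >= 0) & (x < n) & (y >= 0) & (y < n) & (z >= 0) & (z < n)
        if not inside.all():
            clipped = True
        mask[x[inside], y[inside], z[inside]] = 1
    return clipped


def generate_vessel_phantom(params: PhantomParams | None = None) -> tuple[VolumeGrid, VolumeGrid]:
    """Build (vein_mask, artery_mask) binary volumes, world origin at center.

    Veins: ``n_vein_arcs`` great-circle arcs of the skull sphere, azimuthally
    jittered, swept with a ``vein_radius`` tube.  Arteries: a recursively
    bifurcating tree (depth 3) of ``artery_radius`` tubes growing from a
    single inferior inlet.  Tubes reaching outside the grid are clipped with
    a warning.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(params.seed)
    n = params.grid_size
    sp = params.voxel_spacing
    center = (n - 1) / 2.0

    def world_to_vox(pts):
        return pts / sp + center

    clipped = False
    veins = np.zeros((n, n, n), dtype=np.uint8)
    for _ in range(params.n_vein_arcs):
        # arc plane: random axis, slight shrink inside the skull shell
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        # two orthonormal vectors spanning the arc plane
        a = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(axis, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(axis, a)
        phase = rng.uniform(0, 2 * np.pi)
        radius = params.skull_radius * rng.uniform(0.85, 0.98)
        angles = phase + np.linspace(-np.pi / 2, np.pi / 2, 160)  # semicircle
        pts = radius * (np.outer(np.cos(angles), a) + np.outer(np.sin(angles), b))
        clipped |= _stamp_tube(veins, world_to_vox(pts), params.vein_radius / sp)

    arteries = np.zeros((n, n, n), dtype=np.uint8)
    if params.n_artery_branches > 0:
        stack = [(np.array([0.0, 0.0, -0.8 * params.skull_radius]), np.array([0.0, 0.0, 1.0]), 0)]
        while stack:
            start, direction, depth = stack.pop()
            length = params.skull_radius * (0.55 if depth == 0 else 0.4) * rng.uniform(0.8, 1.2)
            end = start + length * direction
            pts = start + np.outer(np.linspace(0, 1, 60), end - start)
            clipped |= _stamp_tube(arteries, world_to_vox(pts), params.artery_radius / sp)
            if depth < 3 - 1:
                for _ in range(min(params.n_artery_branches, 2) if depth else params.n_artery_branches):
                    perturb = rng.normal(size=3) * 0.6
                    child = direction + perturb
                    child /= np.linalg.norm(child)
                    stack.append((end, child, depth + 1))
    if clipped:
        warnings.warn("phantom tubes reached the grid boundary and were clipped")

    vein_grid = VolumeGrid.centered(veins, spacing=sp)
    artery_grid = VolumeGrid.centered(arteries, spacing=sp)
    return vein_grid, artery_grid


def attenuation_volume(
    vein_mask: VolumeGrid,
    artery_mask: VolumeGrid,
    vein_value: float = 1.0,
    artery_value: float = 0.6,
    smooth_sigma: float = 0.7,
) -> VolumeGrid:
    """Grayscale pseudo-CTA: weighted vessel masks, lightly blurred.

    The blur emulates partial-volume softening so that intensity-based
    similarity metrics see gradients rather than hard steps.
    """
    vals = vein_value * vein_mask.values.astype(float) + artery_value * artery_mask.values.astype(float)
    if smooth_sigma > 0:
        vals = gaussian_filter(vals, smooth_sigma)
    return VolumeGrid(values=vals.astype(np.float32), voxel_to_world=vein_mask.voxel_to_world)


def sample_offset(params: OffsetSamplerParams | None = None, rng: np.random.Generator | None = None) -> RigidTransform:
    """One uniform random rigid perturbation.

    Rotation components are drawn per-axis in degrees and composed through
    the axis-angle map; translations are drawn per-axis in mm.
    """
    params = params or OffsetSamplerParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rot_deg = rng.uniform(-1.0, 1.0, size=3) * np.asarray(params.rotation_range)
    trans = rng.uniform(-1.0, 1.0, size=3) * np.asarray(params.translation_range)
    from .se3 import exp  # local import avoids cycle at module load

    return exp(np.concatenate([np.deg2rad(rot_deg), trans]))


def make_training_pair(
    veins: VolumeGrid,
    registered_pose: RigidTransform,
    offset: RigidTransform,
    geom: CArmGeometry,
    renderer: DrrRenderer | None = None,
) -> tuple[Projection2D, Projection2D, RigidTransform]:
    """(fixed, moving, target) for one perturbation.

    fixed  = binarized DRR at the registered pose (synthesized DSA),
    moving = binarized DRR at compose(registered_pose, offset),
    target = invert(offset), the correction the network must predict.
    """
    renderer = renderer or DrrRenderer(veins, geom)
    fixed_raw = renderer.render(pose=registered_pose)
    moving_raw = renderer.render(pose=compose(registered_pose, offset))
    if fixed_raw.values.max() <= 0 or moving_raw.values.max() <= 0:
        raise DegeneratePairError("fixed or moving DRR is empty; resample the offset")
    fixed = binarize(fixed_raw, DRR_BINARIZE_FRACTION * fixed_raw.values.max())
    moving = binarize(moving_raw, DRR_BINARIZE_FRACTION * moving_raw.values.max())
    return fixed, moving, invert(offset)


def training_pairs(
    veins: VolumeGrid,
    registered_pose: RigidTransform,
    geom: CArmGeometry,
    n_pairs: int,
    offset_params: OffsetSamplerParams | None = None,
):
    """Yield ``n_pairs`` training tuples (fixed, moving, offset, target).

    Degenerate draws (empty DRRs) are rejected and resampled, with a log line
    per rejection.
    """
    offset_params = offset_params or OffsetSamplerParams()
    rng = np.random.default_rng(offset_params.seed)
    renderer = DrrRenderer(veins, geom)
    produced = 0
    while produced < n_pairs:
        offset = sample_offset(offset_params, rng=rng)
        try:
            fixed, moving, target = make_training_pair(veins, registered_pose, offset, geom, renderer=renderer)
        except DegeneratePairError:
            log.info("rejected degenerate training pair; resampling offset")
            continue
        produced += 1
        yield fixed, moving, offset, target


def make_dsa_frames(
    attenuation: VolumeGrid,
    pose: RigidTransform,
    geom: CArmGeometry,
    n_frames: int = 5,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> list[Projection2D]:
    """Synthetic DSA run: vessels appear dark on a bright background.

    Each frame is ``1 - DRR/max`` plus independent Gaussian noise, so the
    per-pixel minimum over frames (the MinIP) recovers a low-noise
    vessel-dark composite, as in real subtracted angiography runs.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    drr = DrrRenderer(attenuation, geom).render(pose=pose).values
    base = 1.0 - drr / drr.max() if drr.max() > 0 else np.ones_like(drr)
    frames = []
    for _ in range(n_frames):
        noisy = base + rng.normal(scale=noise_sigma, size=base.shape)
        frames.append(Projection2D(values=noisy, pixel_spacing=geom.pixel_spacing, kind="drr"))
    return frames


def smooth_blob_phantom(grid_size: int = 32, spacing: float = 3.0) -> VolumeGrid:
    """Smooth, compactly supported test volume for gradient checks and demos.

    Two polynomial bumps, Gaussian-smoothed, then tapered to exactly zero
    before the grid faces: the field is continuous everywhere (no boundary
    flux), so analytic pose gradients of its DRR match finite differences.
    """
    x = np.linspace(-1, 1, grid_size)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")

    def bump(cx, cy, cz, r):
        r2 = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / r**2
        return np.where(r2 < 1, (1 - r2) ** 3, 0.0)

    raw = bump(0.12, -0.05, 0.0, 0.5) + 0.6 * bump(-0.18, 0.2, -0.12, 0.35)
    field = gaussian_filter(raw, 3.0)
    rmax = np.maximum.reduce([np.abs(X), np.abs(Y), np.abs(Z)])
    u = np.clip((0.9 - rmax) / 0.3, 0.0, 1.0)
    field = field * (u * u * (3 - 2 * u))
    return VolumeGrid.centered(field.astype(np.float32), spacing=spacing)
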