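"""Shared fixtures: phantom volumes, C-arm geometries, synthesized DSA
targets, and an independent brute-force DRR oracle.

The oracle integrator deliberately shares no code with the package renderer:
it marches every ray with scipy's map_coordinates at a fine fixed step over
a conservatively wide window, so agreement between the two is a genuine
cross-check of the rendering geometry and quadrature.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from angioreg.geometry import CArmGeometry, Projection2D, VolumeGrid
from angioreg.phantom import PhantomParams, generate_vessel_phantom
from angioreg.render import DrrRenderer, binarize
from angioreg.se3 import RigidTransform


def reference_drr(volume: VolumeGrid, pose: RigidTransform, geom: CArmGeometry, step: float = 0.1) -> np.ndarray:
    """Brute-force fine-step ray integrator (test oracle).

    For every detector pixel, samples the trilinear interpolant along the
    source-to-pixel ray at fixed ``step`` (mm) over a window guaranteed to
    contain the volume, via scipy's map_coordinates, and sums.
    """
    src = geom.source_position
    pix = geom.detector_pixel_positions()
    dirs = pix - src
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    corners_world = volume.world_corners()
    corners_carm = corners_world @ pose.rotation.T + pose.translation
    # exact window: ray-parameter extent of every corner along every ray
    t_corners = (corners_carm - src) @ dirs.T
    margin = float(np.linalg.norm(volume.spacing)) + 2 * step  # trilinear support past corner centers
    t = np.arange(t_corners.min() - margin, t_corners.max() + margin, step)

    pts_carm = src[None, None, :] + t[None, :, None] * dirs[:, None, :]
    inv_pose = np.linalg.inv(pose.matrix())
    pts_world = pts_carm @ inv_pose[:3, :3].T + inv_pose[:3, 3]
    w2v = np.linalg.inv(volume.voxel_to_world)
    pts_vox = pts_world @ w2v[:3, :3].T + w2v[:3, 3]
    sampled = map_coordinates(
        np.asarray(volume.values, dtype=float),
        pts_vox.reshape(-1, 3).T,
        order=1,
        mode="grid-constant",  # trilinear decay into the zero surround
        cval=0.0,
    ).reshape(len(dirs), len(t))
    return (sampled.sum(axis=1) * step).reshape(geom.detector_rows, geom.detector_cols)


@pytest.fixture(scope="session")
def geom128() -> CArmGeometry:
    return CArmGeometry(source_to_detector=1000.0, detector_rows=128, detector_cols=128, pixel_spacing=2.0)


@pytest.fixture(scope="session")
def geom64() -> CArmGeometry:
    return CArmGeometry(source_to_detector=1000.0, detector_rows=64, detector_cols=64, pixel_spacing=4.0)


@pytest.fixture(scope="session")
def phantom_masks():
    return generate_vessel_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def vein_volume(phantom_masks) -> VolumeGrid:
    return phantom_masks[0]


@pytest.fixture(scope="session")
def full_vessel_volume(phantom_masks) -> VolumeGrid:
    veins, arteries = phantom_masks
    return VolumeGrid(values=(veins.values | arteries.values), voxel_to_world=veins.voxel_to_world)


@pytest.fixture(scope="session")
def dsa_segmentation(full_vessel_volume, geom128) -> Projection2D:
    """Synthesized binary DSA at the identity (registered) pose."""
    raw = DrrRenderer(full_vessel_volume, geom128).render(pose=RigidTransform())
    return binarize(raw, 1e-6 * raw.values.max())
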