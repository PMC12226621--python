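"""Applying the trained initialization network to a CTA/DSA pair.

The baseline "radiological" pose is built purely from the C-arm gantry
angles; the network then predicts a rigid correction from the pair of binary
vein projections (CTA DRR at the baseline pose, DSA segmentation)."""

from __future__ import annotations

import numpy as np

from ..geometry import CArmGeometry, Projection2D, VolumeGrid
from ..render import DrrRenderer, binarize
from ..se3 import RigidTransform, compose, exp
from .model import PoseRegressionCNN
from .training import _prepare_input

__all__ = ["radiological_pose", "predict_initial_pose"]

# threshold fraction for binarizing a rendered vein DRR: any traversed
# vessel mass counts as foreground
_BIN_FRACTION = 1e-6


def radiological_pose(geom: CArmGeometry) -> RigidTransform:
    """Pose implied by the C-arm angles alone, zero translation.

    Extrinsic convention: first the primary angle (LAO/RAO) about the
    patient longitudinal axis (world z), then the secondary (cranio-caudal)
    angle about the fixed world x axis: ``R = Rx(secondary) @ Rz(primary)``.
    """
    pa = np.deg2rad(geom.primary_angle)
    sa = np.deg2rad(geom.secondary_angle)
    rz = np.array([
        [np.cos(pa), -np.sin(pa), 0.0],
        [np.sin(pa), np.cos(pa), 0.0],
        [0.0, 0.0, 1.0],
    ])
    rx = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(sa), -np.sin(sa)],
        [0.0, np.sin(sa), np.cos(sa)],
    ])
    return RigidTransform(rotation=rx @ rz, translation=np.zeros(3))


def predict_initial_pose(
    network: PoseRegressionCNN,
    volume_veins: VolumeGrid,
    fixed: Projection2D,
    base_pose: RigidTransform,
    geom: CArmGeometry,
) -> RigidTransform:
    """Initial pose T~ = compose(base_pose, exp(network(moving, fixed))).

    Renders the binarized vein DRR at ``base_pose``, stacks it with the
    fixed DSA vein segmentation (both resampled to the network's input size
    with bilinear interpolation and re-binarized at 0.5), and applies the
    predicted chart-vector correction on the right of the base pose.
    """
    raw = DrrRenderer(volume_veins, geom).render(pose=base_pose)
    threshold = _BIN_FRACTION * raw.values.max() if raw.values.max() > 0 else 0.0
    moving = binarize(raw, threshold)
    x = _prepare_input(moving, fixed, network.input_size)
    v = network.predict(x)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("network produced a non-finite pose prediction")
    return compose(base_pose, exp(v))
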