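"""Training of the initialization network on self-synthesized DRR pairs.

Each training pair perturbs a registered vein volume by a random rigid
offset; the network sees (moving, fixed) binary projections and must regress
the inverse offset.  The objective combines a soft-Dice image term — the
moving DRR re-rendered at the *predicted* pose against the fixed image,
differentiated through the renderer — with the two geodesic pose losses:

    loss = DiceLoss(render(pred), fixed)
         + lambda * ( L_geo2(pred, target; f) + L_geo(pred, target) )

where L_geo mixes radians with mm and L_geo2 converts the angular error to
mm via the source-to-detector distance f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..geometry import CArmGeometry, Projection2D, VolumeGrid
from ..optim import Adam
from ..refine import soft_dice, soft_dice_with_gradient
from ..render import DrrRenderer
from ..se3 import (
    RigidTransform,
    compose,
    double_geodesic_loss,
    exp,
    geodesic_loss,
    rotation_jacobian,
)
from .model import PoseRegressionCNN

__all__ = ["InitNetConfig", "composite_loss", "geodesic_terms_gradient", "train_init_network"]

log = logging.getLogger(__name__)

_BACKBONES = {
    "small_resnet": (16, 32, 64),
    "wide_resnet": (32, 64, 128),
}


@dataclass(frozen=True)
class InitNetConfig:
    """Hyperparameters of the initialization network and its training run."""

    backbone: str = "small_resnet"
    input_size: int = 64
    lambda_weight: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if self.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; options: {sorted(_BACKBONES)}")


def composite_loss(
    pred: RigidTransform,
    target: RigidTransform,
    moving_rendered: Projection2D | np.ndarray,
    fixed: Projection2D | np.ndarray,
    f: float,
    lambda_weight: float,
) -> float:
    """Dice loss of the re-rendered moving image plus weighted geodesic terms."""
    dice_loss = 1.0 - soft_dice(moving_rendered, fixed)
    return dice_loss + lambda_weight * (
        double_geodesic_loss(pred, target, f) + geodesic_loss(pred, target)
    )


def geodesic_terms_gradient(v_pred: np.ndarray, target: RigidTransform, f: float):
    """(value, gradient w.r.t. the 6 chart parameters) of L_geo2 + L_geo.

    Closed-form differentiation: both losses depend on the pose only through
    the relative rotation angle theta and the translation difference, so the
    chain runs through d theta / d omega (Rodrigues Jacobian traces) and the
    normalized translation residual.
    """
    v_pred = np.asarray(v_pred, dtype=float).reshape(6)
    pred = exp(v_pred)
    c = np.clip((np.trace(pred.rotation.T @ target.rotation) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(c)
    dt = pred.translation - target.translation
    d2 = dt @ dt
    l_geo = np.sqrt(theta**2 + d2)
    l_geo2 = np.sqrt((f * theta) ** 2 + d2)
    value = float(l_geo + l_geo2)

    grad = np.zeros(6)
    eps = 1e-12
    # translation part
    coeff_t = (1.0 / max(l_geo, eps)) + (1.0 / max(l_geo2, eps)) if (l_geo > eps or l_geo2 > eps) else 0.0
    grad[3:] = dt * coeff_t
    # rotation part: d theta/d omega_k = -(1/sin theta) * d c/d omega_k, with
    # theta/sin(theta) -> 1 guarding the identity
    J = rotation_jacobian(v_pred[:3])
    dc = np.array([0.5 * np.sum(J[k] * target.rotation) for k in range(3)])
    sin_theta = np.sqrt(max(1.0 - c * c, 0.0))
    ratio = theta / sin_theta if sin_theta > 1e-8 else 1.0
    coeff_r = ratio * (1.0 / max(l_geo, eps) + f**2 / max(l_geo2, eps)) if theta > 0 or d2 > 0 else 0.0
    grad[:3] = -dc * coeff_r
    return value, grad


def _prepare_input(moving: Projection2D, fixed: Projection2D, input_size: int) -> np.ndarray:
    """Stack (moving, fixed) as 2 channels, resampled to the network size.

    Bilinear resampling followed by re-binarization at 0.5 preserves the
    binary-segmentation character of the inputs.
    """
    from skimage.transform import resize

    chans = []
    for img in (moving, fixed):
        v = np.asarray(img.values, dtype=float)
        if v.shape != (input_size, input_size):
            v = resize(v, (input_size, input_size), order=1, anti_aliasing=False)
            v = (v > 0.5).astype(float)
        chans.append(v)
    return np.stack(chans)


def train_init_network(
    pairs,
    config: InitNetConfig,
    geom: CArmGeometry,
    veins: VolumeGrid,
    registered_pose: RigidTransform,
) -> tuple[PoseRegressionCNN, list[float]]:
    """Minibatch Adam training on (fixed, moving, offset, target) tuples.

    ``pairs`` is any iterable of tuples as produced by
    :func:`angioreg.phantom.training_pairs`.  Every step re-renders each
    sample's moving DRR at its predicted pose through the differentiable
    renderer, so the Dice term's gradient flows into the pose prediction.
    Returns the trained network and the per-epoch mean loss history.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one training pair")
    net = PoseRegressionCNN(
        widths=_BACKBONES[config.backbone], input_size=config.input_size, seed=config.seed
    )
    if config.epochs == 0:
        return net, []

    renderer = DrrRenderer(veins, geom)
    f = geom.source_to_detector
    inputs = [_prepare_input(moving, fixed, config.input_size) for fixed, moving, _, _ in pairs]
    bases = [compose(registered_pose, offset) for _, _, offset, _ in pairs]
    fixed_full = [np.asarray(fixed.values, dtype=float) for fixed, _, _, _ in pairs]
    targets = [target for _, _, _, target in pairs]

    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    n = len(pairs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = np.stack([inputs[i] for i in idx])
            v_pred = net.forward(x)
            dout = np.zeros_like(v_pred)
            batch_loss = 0.0
            for row, i in enumerate(idx):
                v_i = v_pred[row]
                rendered = renderer.render(base_pose=bases[i], v=v_i)
                dice, ddice_dimg = soft_dice_with_gradient(rendered.values, fixed_full[i])
                grad_dice = renderer.pose_gradient(bases[i], v_i, -ddice_dimg)
                geo_val, geo_grad = geodesic_terms_gradient(v_i, targets[i], f)
                loss_i = (1.0 - dice) + config.lambda_weight * geo_val
                if not np.isfinite(loss_i):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, sample {i}: "
                        f"dice={dice!r}, geo={geo_val!r}, v_pred={v_i!r}"
                    )
                batch_loss += loss_i
                dout[row] = (grad_dice + config.lambda_weight * geo_grad) / len(idx)
            net.backward(dout)
            opt.step(net.grads)
            epoch_losses.append(batch_loss / len(idx))
        history.append(float(np.mean(epoch_losses)))
        log.info("epoch %d/%d: mean loss %.4f", epoch + 1, config.epochs, history[-1])
    return net, history
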