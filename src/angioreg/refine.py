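"""Similarity metrics and the two iterative pose-refinement stages.

Stage 1 renders the full CTA vessel segmentation and ascends normalized
cross-correlation (NCC) against the binary DSA segmentation; stage 2 starts
from stage 1's answer, renders the grayscale CTA and ascends mutual
information (MI) against the DSA minimum-intensity projection with step
sizes scaled down.  Both stages run a fixed Adam iteration budget on the
6 pose chart parameters and return the pose with the *highest similarity
seen anywhere in the trace*, not the final iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CArmGeometry, Projection2D, VolumeGrid
from .optim import Adam
from .render import DrrRenderer
from .se3 import RigidTransform, compose, exp

__all__ = [
    "RefineConfig",
    "RefineTrace",
    "RegistrationResult",
    "ZeroVarianceError",
    "ncc",
    "ncc_with_gradient",
    "soft_dice",
    "soft_dice_with_gradient",
    "mutual_information",
    "soft_mutual_information_with_gradient",
    "refine_stage",
    "run_pipeline",
]


class ZeroVarianceError(ValueError):
    """NCC is undefined for a constant image."""


def _vals(img) -> np.ndarray:
    return np.asarray(img.values if isinstance(img, Projection2D) else img, dtype=float)


# -- normalized cross-correlation --------------------------------------------

def ncc(a, b) -> float:
    """Global Pearson correlation of two equally shaped images, in [-1, 1]."""
    av, bv = _vals(a), _vals(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    ac = av - av.mean()
    bc = bv - bv.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        raise ZeroVarianceError("NCC undefined: an input image is constant")
    return float((ac * bc).mean() / (sa * sb))


def ncc_with_gradient(a, b):
    """(ncc, d ncc / d a) for gradient ascent on the first image."""
    av, bv = _vals(a), _vals(b)
    n = av.size
    ac = av - av.mean()
    bc = bv - bv.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        raise ZeroVarianceError("NCC undefined: an input image is constant")
    ahat, bhat = ac / sa, bc / sb
    s = float((ahat * bhat).mean())
    grad = (bhat - s * ahat) / (n * sa)
    return s, grad


# -- soft Dice ----------------------------------------------------------------

_DICE_EPS = 1e-6


def soft_dice(a, b) -> float:
    """Soft Dice overlap 2*sum(ab)/(sum a + sum b), smoothed by eps."""
    av, bv = _vals(a), _vals(b)
    num = 2.0 * (av * bv).sum() + _DICE_EPS
    den = av.sum() + bv.sum() + _DICE_EPS
    return float(num / den)


def soft_dice_with_gradient(a, b):
    """(dice, d dice / d a)."""
    av, bv = _vals(a), _vals(b)
    num = 2.0 * (av * bv).sum() + _DICE_EPS
    den = av.sum() + bv.sum() + _DICE_EPS
    grad = (2.0 * bv * den - num) / den**2
    return float(num / den), grad


# -- mutual information --------------------------------------------------------

def _normalize01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)


def mutual_information(a, b, bins: int = 32) -> float:
    """Hard-binned MI of the joint intensity histogram, in nats.

    Intensities are min-max scaled to [0, 1]; constant images carry zero
    marginal entropy and give MI = 0.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    av, bv = _vals(a).ravel(), _vals(b).ravel()
    if av.shape != bv.shape:
        raise ValueError("shape mismatch")
    joint, _, _ = np.histogram2d(_normalize01(av), _normalize01(bv), bins=bins, range=[[0, 1], [0, 1]])
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / (pa @ pb)[mask])).sum())


def soft_mutual_information_with_gradient(a, b, bins: int = 32):
    """(MI, d MI / d a) with Gaussian soft binning (sigma = one bin width).

    The differentiable surrogate used during stage-2 optimization; the
    normalization constants of both images are treated as fixed.
    """
    av, bv = _vals(a), _vals(b)
    shape = av.shape
    af, bf = av.ravel(), bv.ravel()
    n = af.size
    lo, hi = af.min(), af.max()
    scale_a = 0.0 if hi == lo else 1.0 / (hi - lo)
    an = (af - lo) * scale_a
    bn = _normalize01(bf)
    centers = (np.arange(bins) + 0.5) / bins
    sigma = 1.0 / bins
    # per-pixel normalized Gaussian bin weights
    da = (an[:, None] - centers[None, :]) / sigma
    wa = np.exp(-0.5 * da**2)
    za = wa.sum(axis=1, keepdims=True)
    wa_n = wa / za
    db = (bn[:, None] - centers[None, :]) / sigma
    wb = np.exp(-0.5 * db**2)
    wb_n = wb / wb.sum(axis=1, keepdims=True)

    p = (wa_n.T @ wb_n) / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    eps = 1e-12
    logterm = np.log((p + eps) / (pa @ pb + eps))
    mi = float((p * logterm).sum())

    # dMI/dp_ij = log(p/(pa*pb)) (the +1/-1 entropy terms cancel through sum p = 1)
    # chain to a through the normalized weights
    dwa = wa * (-da / sigma)                     # d w_i / d an
    dza = dwa.sum(axis=1, keepdims=True)
    dwa_n = (dwa * za - wa * dza) / za**2        # d (w_i/z) / d an
    grad_an = ((dwa_n @ logterm) * wb_n).sum(axis=1) / n
    grad = (grad_an * scale_a).reshape(shape)
    return mi, grad


# -- refinement ----------------------------------------------------------------

@dataclass(frozen=True)
class RefineConfig:
    """One refinement stage's settings.

    rotation_step / translation_step are Adam learning rates for the two
    parameter groups (radians and mm); ``step_scale_stage2`` multiplies both
    in the second stage, which the pipeline builds via :meth:`scaled`.
    """

    n_iterations: int = 250
    rotation_step: float = 0.01
    translation_step: float = 1.0
    similarity: str = "ncc"
    mi_bins: int = 32
    step_scale_stage2: float = 0.1
    # saturate rendered path lengths I -> I/(I + c) before the similarity:
    # a differentiable stand-in for binarization, so a grayscale DRR can be
    # compared against a binary DSA segmentation with its optimum at the
    # true pose.  None disables (used for MI against grayscale MinIPs).
    drr_saturation: float | None = 0.5

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.rotation_step <= 0 or self.translation_step <= 0:
            raise ValueError("step sizes must be positive")
        if self.similarity not in ("ncc", "mi", "dice"):
            raise ValueError("similarity must be one of ncc/mi/dice")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if not (0 < self.step_scale_stage2 <= 1):
            raise ValueError("step_scale_stage2 must be in (0, 1]")

    def scaled(self, factor: float) -> "RefineConfig":
        return replace(
            self,
            rotation_step=self.rotation_step * factor,
            translation_step=self.translation_step * factor,
        )


@dataclass
class RefineTrace:
    """Per-iteration poses and similarity values of one stage."""

    poses: list = field(default_factory=list)
    similarities: list = field(default_factory=list)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.similarities))

    @property
    def best_similarity(self) -> float:
        return float(self.similarities[self.best_index])


@dataclass
class RegistrationResult:
    """All per-stage poses/traces of one pipeline run, plus optional MPEs."""

    initial_pose: RigidTransform
    stage1_pose: RigidTransform | None = None
    stage2_pose: RigidTransform | None = None
    stage1_trace: RefineTrace | None = None
    stage2_trace: RefineTrace | None = None
    mpe_before: float | None = None
    mpe_after_init: float | None = None
    mpe_after_stage1: float | None = None
    mpe_after_stage2: float | None = None
    two_stage_only: bool = False

    @property
    def final_pose(self) -> RigidTransform:
        for p in (self.stage2_pose, self.stage1_pose, self.initial_pose):
            if p is not None:
                return p
        raise RuntimeError("empty result")

    def success(self, threshold: float) -> bool | None:
        if self.mpe_after_stage2 is not None:
            return self.mpe_after_stage2 < threshold
        if self.mpe_after_stage1 is not None:
            return self.mpe_after_stage1 < threshold
        return None


def _similarity_fn(config: RefineConfig):
    if config.similarity == "ncc":
        return lambda img, fixed: ncc_with_gradient(img, fixed)
    if config.similarity == "dice":
        return lambda img, fixed: soft_dice_with_gradient(img, fixed)
    return lambda img, fixed: soft_mutual_information_with_gradient(img, fixed, bins=config.mi_bins)


def refine_stage(
    volume: VolumeGrid,
    fixed: Projection2D,
    start_pose: RigidTransform,
    geom: CArmGeometry,
    config: RefineConfig,
    renderer: DrrRenderer | None = None,
) -> tuple[RigidTransform, RefineTrace]:
    """Adam ascent of a similarity metric over the 6 pose parameters.

    The pose is parametrized locally as ``compose(start_pose, exp(v))`` with
    ``v`` initialized at zero; each iteration re-renders the DRR, evaluates
    the similarity and its analytic pose gradient, and steps.  Returns the
    best-similarity pose of the whole trace.
    """
    renderer = renderer or DrrRenderer(volume, geom)
    sim = _similarity_fn(config)
    v = np.zeros(6)
    opt = Adam(
        [v],
        lr=[np.array([config.rotation_step] * 3 + [config.translation_step] * 3)],
    )
    trace = RefineTrace()
    c = config.drr_saturation
    for it in range(config.n_iterations):
        img = renderer.render(base_pose=start_pose, v=v)
        raw = img.values
        vals = raw / (raw + c) if c else raw
        try:
            s, ds_dimg = sim(vals, fixed.values)
        except ZeroVarianceError:
            if it == 0:
                raise
            warnings.warn("similarity became undefined mid-run; returning best pose so far")
            break
        if not np.isfinite(s):
            if it == 0:
                raise FloatingPointError("similarity non-finite at the starting pose")
            warnings.warn("similarity became non-finite mid-run; returning best pose so far")
            break
        trace.poses.append(compose(start_pose, exp(v)))
        trace.similarities.append(float(s))
        if c:
            ds_dimg = ds_dimg * c / (raw + c) ** 2
        grad_v = renderer.pose_gradient(start_pose, v, ds_dimg)
        opt.step([-grad_v])  # ascend
    best = trace.poses[trace.best_index]
    return best, trace


def run_pipeline(
    cta_veins: VolumeGrid,
    cta_full_vessels: VolumeGrid,
    dsa_seg: Projection2D,
    dsa_minip: Projection2D | None,
    geom: CArmGeometry,
    network=None,
    stage1_config: RefineConfig | None = None,
    stage2_config: RefineConfig | None = None,
    cta_attenuation: VolumeGrid | None = None,
    reference_pose: RigidTransform | None = None,
    base_pose: RigidTransform | None = None,
) -> RegistrationResult:
    """Full multistage registration.

    Stage 0 takes the initial pose from the trained network (or falls back
    to the radiological pose); stage 1 refines it with NCC against the DSA
    segmentation using the full vessel volume; stage 2 continues from stage
    1 with MI against the MinIP using the grayscale CTA (the vessel volume
    if no attenuation CTA is given) at step sizes scaled by
    ``step_scale_stage2``.  If a reference pose is supplied, mean projection
    errors before/after every stage are recorded.
    """
    from .network.inference import predict_initial_pose, radiological_pose

    stage1_config = stage1_config or RefineConfig(similarity="ncc")
    if stage2_config is None:
        stage2_config = RefineConfig(similarity="mi", drr_saturation=None).scaled(
            stage1_config.step_scale_stage2
        )

    if base_pose is None:
        base_pose = radiological_pose(geom)
    if network is not None:
        initial = predict_initial_pose(network, cta_veins, dsa_seg, base_pose, geom)
    else:
        initial = base_pose

    result = RegistrationResult(initial_pose=initial)

    def _mpe(pose):
        from .evaluate import mpe

        return mpe(reference_pose, pose, cta_veins, geom)

    if reference_pose is not None:
        result.mpe_before = _mpe(base_pose)
        result.mpe_after_init = _mpe(initial)

    result.stage1_pose, result.stage1_trace = refine_stage(
        cta_full_vessels, dsa_seg, initial, geom, stage1_config
    )
    if reference_pose is not None:
        result.mpe_after_stage1 = _mpe(result.stage1_pose)

    if dsa_minip is None:
        result.two_stage_only = True
        return result

    stage2_volume = cta_attenuation if cta_attenuation is not None else cta_full_vessels
    result.stage2_pose, result.stage2_trace = refine_stage(
        stage2_volume, dsa_minip, result.stage1_pose, geom, stage2_config
    )
    if reference_pose is not None:
        result.mpe_after_stage2 = _mpe(result.stage2_pose)
    return result
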