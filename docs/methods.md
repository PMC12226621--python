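# Methods

`angioreg` registers a 3D cerebral CTA (or its binary vessel segmentation)
to a single 2D DSA view by estimating the rigid pose that places the volume
in the C-arm frame. The pipeline has three stages, each consuming
progressively more image detail:

1. **Learned initialization.** A small CNN sees the pair (binarized vein DRR
   rendered at the baseline pose, binary DSA vein segmentation) and
   regresses a rigid correction. It is trained entirely on self-synthesized
   data: the registered vein volume is perturbed by random offsets, and the
   network learns to predict each offset's inverse.
2. **Segmentation refinement.** Adam ascent of normalized cross-correlation
   between the rendered full-vessel DRR and the binary DSA segmentation.
3. **Intensity refinement.** Adam ascent of mutual information between the
   grayscale CTA DRR and the DSA minimum-intensity projection, at step
   sizes scaled down by `step_scale_stage2`.

Both refinement stages return the pose with the highest similarity seen
anywhere in the trace, not the final iterate.

## Pose representation

A pose is a proper rotation plus a translation in mm, mapping volume world
coordinates into the C-arm frame (origin at the isocenter, source at
`(0, 0, -source_to_isocenter)`, detector plane orthogonal to +z).
Optimization and network output use a 6-parameter chart: an axis-angle
rotation vector (radians) and the translation taken directly. `exp` is the
Rodrigues formula on the rotation block only; `log` is its inverse on the
principal branch (angle < π, where the chart raises rather than choosing a
branch silently). We deliberately do not couple translation to rotation
through the SE(3) V-matrix: the chart is only a parametrization, the
geodesic losses below treat rotation and translation separately anyway, and
the decoupled form keeps the renderer's pose Jacobian short. All stated
invariants (exp(0)=I, exp∘log=id within 1e-8) hold in this chart.

Two pose distances serve as training losses:

- geodesic: `sqrt(θ² + ‖Δt‖²)` with `θ = arccos((tr(RaᵀRb) − 1)/2)`
  (the trace argument is clamped to [−1, 1] against floating-point drift);
- double geodesic: `sqrt((f·θ)² + ‖Δt‖²)`, where the source-to-detector
  distance `f` converts the angular error into millimetres of detector
  displacement, putting both terms in one unit.

## Differentiable DRR rendering

Each detector pixel integrates the volume's trilinear interpolant along the
ray from the source to the pixel center, by the midpoint rule at a fixed
step (default: half the smallest voxel spacing). Three details matter for
correctness:

- **Zero padding.** The volume is padded by one zero voxel so the
  interpolated field decays continuously to zero over the voxel beyond each
  boundary voxel center (the `grid-constant` convention). Without this the
  field is discontinuous at the volume face and the integral acquires a
  boundary-flux derivative that the sampled gradient cannot represent.
- **Foreground clipping with a fixed comb.** Rays are clipped to the padded
  bounding box of the nonzero voxels, but sample positions are snapped to
  absolute multiples of the step. The sampling comb therefore never shifts
  with the pose — window edges only gain or lose zero-valued samples — so
  the quadrature error's phase does not leak into the pose gradient.
- **Analytic pose gradients.** Poses are written `compose(base, exp(v))`;
  the gradient of any scalar image functional with respect to `v` chains
  the per-sample trilinear spatial gradient through the affine and the
  closed-form Rodrigues Jacobian (Gallego–Yezzi). Per ray only two 3-vector
  accumulators are needed, so the gradient pass costs about one render.
  On a smooth, compactly supported 32³ phantom the gradient of the mean
  DRR intensity agrees with central finite differences (step 1e-4) to an
  aggregate relative error of ~6e-4; the residual is finite-difference
  noise from the trilinear field's derivative kinks, which vanishes as the
  step shrinks.

The rendering itself agrees with an independent fine-step integrator
(scipy `map_coordinates` marched at 0.05 mm) to < 1e-3 maximum relative
error on random binary 8³ volumes; the tests render at a 0.25 mm step for
this comparison and use the half-voxel default elsewhere, where ~1%
quadrature error is irrelevant next to the similarity landscape.

## Initialization network and training

The backbone is a compact residual CNN over NumPy (im2col convolutions with
hand-written backward passes): a strided stem convolution, two strided
residual blocks (default widths 16→32→64), global average pooling, and two
parallel linear heads for rotation and translation. Head outputs are scaled
by fixed constants (0.1 rad, 10 mm per unit activation) and the final-layer
weights start near zero, so an untrained network predicts approximately the
identity correction. The network operates on 2-channel 64×64 inputs
(moving DRR, fixed segmentation), bilinearly resampled and re-binarized at
0.5 when sizes differ.

The training loss per sample is

    DiceLoss(render(base∘exp(v_pred)), fixed) + λ·(L_geo2(pred, target; f) + L_geo(pred, target))

with soft Dice `2Σab/(Σa+Σb+ε)`, `ε = 1e-6` so two empty images count as a
perfect match. The Dice term re-renders the moving DRR at the predicted
pose every step; its gradient flows through the renderer's pose Jacobian
into the network. The geodesic terms are differentiated in closed form
(`θ/sinθ → 1` guarded at the identity). Defaults: λ = 0.1, Adam at 1e-3,
batch 8, training from scratch. Training is deterministic given the config
seed (NumPy generators only; no threading nondeterminism observed on one
CPU).

Smoke-scale study conditions, chosen once for a desk-scale phantom run:
50 training pairs at 64×64 with offsets uniform in ±15° and ±30 mm per
axis, 40 epochs. Under these conditions the initialization roughly halves
the median misalignment of 20–40 px offsets, which is what the capture-band
tests assert; a real deployment would train far longer on far more pairs.

## Iterative refinement

Each stage optimizes the 6 chart parameters of a local correction around
its start pose with Adam (rotation and translation step sizes are separate
learning rates, defaults 0.01 rad and 1.0 mm; stage 2 scales both by 0.1,
its "smaller steps"). The iteration budget is fixed (default 250); there is
no early stopping, and the best-similarity pose wins.

Stage 1 compares the rendered path-length image against a *binary*
segmentation. Raw path lengths correlate poorly with a binary mask — the
NCC optimum sits visibly off the true pose — so the rendered image is
passed through the saturation `I → I/(I + c)` (default `c` = 0.5 mm of
vessel path) before the similarity: a differentiable stand-in for
binarization whose optimum coincides with the true pose to well under a
pixel. Stage 2 disables the saturation and compares the grayscale DRR
against the MinIP with soft-binned mutual information (32 bins, Gaussian
kernels of one bin width; hard binning is used when only the value is
needed). NCC on a constant image raises; the pipeline treats that as a
configuration error rather than falling back silently.

On the phantom, stage 1 converges from ~10 px initial error to ~1 px
essentially always, holds to roughly 20–25 px, and fails beyond 30–40 px —
the capture-range cliff that motivates the learned initialization.

## Synthetic phantom

The phantom stands in for cerebral CTA anatomy at the level the pipeline
cares about: thick semicircular vein arcs near a 50 mm "skull" sphere
(great-circle arcs of a jittered shell, swept with 4 mm tubes) and a thinner
(2 mm) bifurcating arterial tree of depth 3 growing from an inferior inlet,
on a 64³ grid at 2 mm spacing. DSA runs are emulated as inverted normalized
DRRs with per-frame Gaussian noise, so the MinIP is a vessel-dark composite.
Deliberately absent: real vascular topology (no Circle of Willis), contrast
flow dynamics, motion artifacts, soft-tissue background, and inter-patient
variability. Tests passing on this phantom demonstrate the geometry,
gradients, optimization, and training machinery; they do not demonstrate
clinical accuracy on patient data.

## Evaluation

The mean projection error (MPE) projects the eight corners of the volume's
bounding box under reference and estimated poses and averages the detector
distances, in pixels by default (the mm variant multiplies by the pixel
spacing, which is always an input, never a constant). Corners behind the
source invalidate the evaluation. Capture-range analysis sorts many
(before, after) records into equal-count bins — earlier bins absorb the
remainder, deterministically — and tracks per-bin medians; the divergence
point is the left edge of the first bin whose median exceeds the success
level with no later recovery. Success thresholds are caller-supplied; both
px and mm conventions are supported since the field uses both
interchangeably.

Reader-study tallying counts scores 1–2 as a preference for the left
method, 4–5 for the right, 3 as a tie, and tests each method pair with a
two-sided Wilcoxon signed-rank test whose null distribution is computed
exactly (subset-sum dynamic programming over tie-averaged doubled ranks,
zeros dropped) up to n = 25, with the normal approximation beyond.

## Numerical choices and degenerate inputs

- arccos arguments clamped to [−1, 1]; `log` raises within 1e-6 of a half-turn.
- All-zero volumes render all-zero images silently; a volume posed outside
  the frustum renders zero with a warning.
- Empty training DRRs reject the pair and resample the offset.
- Equal-count binning with indivisible counts gives earlier bins one extra
  record.
- Every stochastic component draws from an explicit seeded NumPy generator;
  the CLI fans one global seed out via SHA-256 of (seed, module name).

## Known limitations

- The renderer models a monoenergetic line integral: no spectra, scatter,
  or detector physics.
- The backbone is far smaller than production pose-regression networks; at
  phantom scale that is enough to show the capture-range mechanism, not to
  saturate accuracy.
- Single-view registration only; depth translation is weakly constrained by
  a lateral view, which is visible in the phantom results as residual
  z-error after convergence in the detector plane.
- The exact-signed-rank implementation enumerates by DP, which is exact but
  limited to the small n of reader studies by design.
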