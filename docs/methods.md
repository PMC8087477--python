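# Methods

This note documents the model implemented by `symreg`, the numerical
conventions it fixes, the rationale for defaults, and what the synthetic
tests do and do not establish.

## Symmetric formulation

Given a template image I^T and subject image I^S on a common voxel grid
(skull-stripped and affinely pre-aligned, so residual deformations are a
few voxels), a fully convolutional network predicts one halfway
displacement field φᵀ.  The subject-side field is constructed, not
predicted: φˢ = −φᵀ, bit-exactly, at every stage.  Both images are pulled
into the pseudomean space by a spatial-transformer warp

    𝒯(I, φ)(u) = Σ_{v ∈ N(u+φ(u))} I(v) Π_d (1 − |u_d + φ_d(u) − v_d|),

the multilinear interpolation over the 2^D corners of the cell containing
the sample point.  All displacements are in voxel units.

### Warp conventions

* **Pull-back semantics.** `warp(I, φ)(u) = I(u + φ(u))`: φ maps output
  coordinates to input coordinates.  Consequently the field that carries
  the *subject image into template space* is the one whose coordinates run
  template → subject.
* **Boundary rule.** Sample coordinates are clamped to the grid (border
  replication).  Interpolation weights are therefore always non-negative
  and sum to 1, so warped intensities never leave the input range and
  gradients stay defined; the derivative of a clamped coordinate is zero.
* **Tie-break.** At exactly-integer sample coordinates the floor-based cell
  is used; the weights then select the integer voxel exactly, which makes
  the zero-field warp a bit-exact identity.
* **Labels** are resampled nearest-neighbour (rounding by `np.rint`, ties
  to even), so the output label set is always a subset of the input's.

## Field algebra

* **Composition.** `compose(outer, inner)(u) = inner(u) + outer(u + inner(u))`,
  i.e. deformation maps satisfy T_c = T_outer ∘ T_inner.  The opposite
  ordering convention exists in other toolkits, so the convention string is
  written into every serialized field's JSON sidecar.
* **Inversion.** The inverse displacement is computed by fixed-point
  iteration ψ ← −φ(u + ψ(u)) from ψ₀ = −φ, stopping when the largest
  update falls below `tol` (default 1e-3 voxel) or after `max_iter`
  (default 30) sweeps.  For smooth fields with displacements up to ~3
  voxels the composition residual `compose(φ, ψ)` is far below 0.1 voxel
  away from the boundary; within a boundary band of roughly the
  displacement magnitude, clamping makes exact inversion impossible and
  residuals are larger.  Non-convergence sets a `converged=False` flag on
  the result instead of raising — a training loop must not die because one
  intermediate field was hard to invert.
* **Forward/backward deformations.**  With pull-back warping, the field
  warping the subject into template space is
  `forward = compose(−φᵀ, invert(φᵀ))` and its counterpart is
  `backward = compose(φᵀ, invert(−φᵀ))`.  The literature writes such
  compositions with both orderings depending on whether fields are read as
  push or pull maps; we fix the convention by its effect: `warp(I_S,
  forward)` lives in template space, and the same `forward` field is used
  by the end-space training loss and by Dice evaluation, so training and
  evaluation optimize and measure the same object.
* **Jacobians and folds.** The Jacobian of the deformation map
  u ↦ u + φ(u) uses central differences in the interior and one-sided
  differences at the boundary; the identity field yields determinant 1
  everywhere.  Folds are counted as interior voxels with negative
  determinant; the one-voxel boundary shell is excluded because its
  one-sided stencil reflects extrapolation, not local topology.  (The
  determinant is taken of the *forward* deformation map — the quantity the
  fold count is defined on.)
* The forward-difference `spatial_gradient` (zero on the final slice of
  each axis) is the stencil shared with the antifold penalty.

## The loss

All similarity terms are SSD normalized by voxel count (a mean, not a sum),
so loss magnitudes — and the printed weights α = 1, β = 0.01, γ = 100 —
remain meaningful across resolutions.  Intensities are min–max normalized
to [0, 1] per volume before any loss is evaluated; this happens once when
the pair input is assembled, and the loss functions themselves never
rescale.

* **Pseudomean similarity**: mean squared difference between
  `warp(I_S, −φᵀ)` and `warp(I_T, φᵀ)`.
* **End-space similarities**: mean squared differences between
  `warp(I_S, forward)` and I^T, and `warp(I_T, backward)` and I^S.
* **Laplace smoothness**: second central differences summed over axes,
  squared, summed over vector components, averaged over *interior* voxels
  (the stencil is undefined on the boundary).  Exactly zero for affine
  fields.  The component convention (sum over components, mean over
  voxels) matches the zero-constraint convention below.
* **Zero constraint**: mean over voxels of ‖φ(u)‖² — the vector norm
  squared, i.e. a constant field (1, 2, 2) scores 9.
* **Antifold**: for each axis d, Q = Δ_d φ_d + 1 (forward difference), the
  approximate diagonal Jacobian entry; penalty R(Q) = |Q| where Q ≤ 0 and
  0 otherwise, summed over axes and voxels and divided by the voxel count.
  Off-diagonal derivatives do not enter.  Zero whenever every same-axis
  derivative exceeds −1.

### Gradients

No autodiff framework is used; each term's gradient with respect to φᵀ is
derived by hand and verified against finite differences in
`tests/test_gradients.py`:

* the warp gradient is the analytic spatial derivative of the multilinear
  interpolant at the sample point (zero where clamped);
* the Laplacian stencil with zero padding is self-adjoint, so the
  smoothness gradient is the same operator applied twice around the
  interior mask;
* the antifold subgradient takes dR/dQ = −1 for Q < 0 and 0 at the kink.

**Stopped gradient through inversion.** The end-space terms contain
`invert(·)` inside a composition.  During training the inverse fields are
treated as constants of the current iterate: gradients flow through the
directly resampled halfway field and through the warped image, not through
the fixed-point iterations.  Backpropagating through the iterations would
require unrolled adjoints for marginal benefit (the inverse changes slowly
between steps); the end-space terms can be disabled entirely with
`TrainingConfig(include_endspace_losses=False)`.  Training-time inversions
use a fixed 5 iterations to bound cost; inference uses the full-tolerance
setting.

## Network

A VoxelMorph-style encoder–decoder: stride-2 3^D convolutions (LeakyReLU
0.2) halve the resolution per level; the decoder applies stride-1
convolutions, nearest-neighbour upsampling and skip concatenation with the
encoder features (finally with the input itself), then optional full-
resolution convolutions and a linear displacement head.  Defaults are a
half-width variant for desk-scale grids: encoder (8, 16, 16, 16), decoder
(16, 16, 16, 16, 8); input extents must be divisible by 2^levels (16 for
the default).  The input is the 3-channel stack (template, subject,
difference map), where the difference map is the signed difference of the
normalized intensities, template − subject.  Channel order is fixed and
recorded in checkpoint metadata; no output symmetry under swapping
template and subject is assumed.

* **Near-identity initialization.** The head weights start at σ = 1e-5
  (bias 0), so an untrained network predicts |φ| ≪ 0.1 voxel — training
  starts from the identity transform, the standard stabilizer for
  unsupervised registration.
* **field_scale** (default 5) multiplies the raw head output.  With
  near-zero initialization and short schedules, the reachable displacement
  magnitude is roughly proportional to this scale; 5 comfortably covers
  the few-voxel deformations of affinely pre-aligned brains (and of the
  phantoms) without destabilizing training, since Adam's per-parameter
  normalization makes the update size invariant to the scale itself.
* Batch size is 1 (pairwise registration of full volumes); weight
  initialization is seeded and inference is deterministic.

## Training schedule

Stage 1 fixes one cohort member as template and pairs it with every member
(n pairs, self-pair included), running 200 Adam steps per pair at lr 1e-4.
Stage 2 enumerates all ordered pairs — n² with self-pairs included
(self-pairs act as identity-regularizing examples; a leave-self-out mode
with n·(n−1) pairs is a config switch) — for 20 epochs at lr 1e-5, halved
every 2 epochs (epoch 4 runs at 2.5e-6).  Pair order in stage 2 is
reshuffled each epoch from the run seed.  Adam uses the common defaults
β₁ = 0.9, β₂ = 0.999, ε = 1e-8.  With a fixed seed and single-threaded
numpy, two runs produce identical loss histories.  A non-finite loss
aborts immediately, naming the stage, pair and step.

## Synthetic phantoms

A phantom "head" is piecewise-smooth tissue on a 2-D or 3-D grid: a bright
outer ellipsoidal shell (skull/scalp analog), a dark ring beneath it (CSF
analog), homogeneous parenchyma, and `n_rois` ellipsoidal blobs with
distinct intensities that double as labeled ROIs.  Intensities are
smoothed with a σ = 1 voxel Gaussian (interfaces are not voxel-sharp) and
carry additive Gaussian noise (default SD 0.01 on a [0, 1] intensity
scale — mild, as for preprocessed MR).

The ground-truth deformation is per-component white noise smoothed with a
Gaussian of width `smoothness_sigma` (default 6 voxels), attenuated by a
broad Gaussian window (σ = 0.45 in normalized coordinates) centred on the
head, and rescaled so the peak displacement magnitude equals
`deformation_amplitude` (default 3 voxels).  The window exists because an
unwindowed random field frequently peaks in the empty background, leaving
the anatomy essentially undeformed — the amplitude is meant to describe
deformation of the anatomy.  Fields are redrawn (bounded retries) until
fold-free, so `subject = warp(template, true_field) + noise` holds by
construction with a topology-preserving truth.  Cohorts share one blob
layout with per-member jitter of head axes, blob positions, radii and
intensities, so ROI k corresponds across members.

**What a green phantom test establishes** is the correctness of the
machinery: the algebra, the losses and their gradients, and that the
unsupervised objective can recover a known smooth deformation at desk
scale.  It does not establish clinical-grade accuracy: phantoms lack real
anatomical geometry, bias fields, Rician noise and partial-volume effects,
and the desk-scale schedule (2-D 64×64, stage 1 only) is far below the
full-scale regime (192×224×192 volumes, 900 training pairs, GPU-scale
budgets).

## Degenerate inputs and edge cases

* Volumes must have every extent ≥ 4 (finite-difference stencils need an
  interior); intensity volumes must be finite; fields must be finite with
  one component per spatial axis.
* A constant-intensity volume min–max normalizes to all zeros.
* ROIs present in only one label map score Dice 0 and are flagged in the
  report (silently dropping them would inflate the mean); Dice means are
  unweighted over ROIs.
* Displacements are stored and reported in voxel units; anisotropic
  spacing only rescales Jacobian derivatives and is off by default (all
  test data are isotropic).

## Known limitations

* Displacement fields are predicted directly; there is no diffeomorphic
  (stationary-velocity / scaling-and-squaring) parameterization, so
  fold-freeness is encouraged by the penalties, not guaranteed.
* No cross-correlation similarity; SSD assumes comparable intensity
  distributions (the min–max normalization is a crude surrogate for
  histogram matching).
* The numpy implementation is single-threaded and CPU-bound; it is built
  for correctness and desk-scale experiments, not for 1 mm whole-brain
  registration throughput.
* Gradient flow through the fixed-point inversion is not implemented (see
  above); the end-space losses are correspondingly approximate as training
  signals, though exact as reported values.
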