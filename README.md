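# symreg — symmetric deformable registration via a learned pseudomean

`symreg` is an unsupervised deep-learning framework for pairwise deformable
registration of skull-stripped, affinely pre-aligned 3-D (or 2-D) brain MR
volumes.  It is aimed at researchers who need dense, inverse-consistent,
fold-free correspondences between image pairs — for atlas building,
population analysis, or longitudinal studies — without ground-truth
deformations for supervision.

## The model

Instead of predicting one long deformation from subject to template, a
convolutional encoder–decoder predicts a single **halfway displacement
field** φᵀ that moves the *template* toward an intermediate **pseudomean
space**; the subject's halfway field is constructed as its exact negation,

&nbsp;&nbsp;&nbsp;&nbsp;φˢ = −φᵀ,

so both images travel equal distances in opposite directions and meet in
the middle.  Full deformations follow by field composition and fixed-point
inversion:

&nbsp;&nbsp;&nbsp;&nbsp;F = φˢ ∘ (φᵀ)⁻¹ (subject → template), F⁻¹ = φᵀ ∘ (φˢ)⁻¹ (template → subject),

which makes inverse consistency a property of the construction rather than
an extra penalty.  Training minimizes a six-term loss,

&nbsp;&nbsp;&nbsp;&nbsp;ℒ = ℒ_sim^sym + ℒ_sim^{S→T} + ℒ_sim^{T→S} + α ℒ_Laplace + β ℒ_zero + γ ℒ_antifold,

with mean-squared-difference (SSD) similarity measured in the pseudomean
space and in both end spaces, a squared-Laplacian smoothness penalty, a
penalty on displacement magnitude, and an antifolding penalty on the
diagonal Jacobian entries of the deformation map; defaults α = 1, β = 0.01,
γ = 100.  Warping is a differentiable spatial transformer (trilinear /
bilinear interpolation with clamped boundaries).  Training runs in two
stages: one-template-vs-all pretraining (200 Adam steps per pair, lr 1e-4),
then all ordered pairs (20 epochs, lr 1e-5 halved every 2 epochs).

Registration quality is scored by per-ROI Dice overlap of warped label
maps, and field regularity by the count of voxels whose Jacobian
determinant J_φ(u) is negative (folds).

The entire stack — network, spatial transformer, loss gradients, Adam — is
implemented in numpy/scipy with hand-derived backpropagation (verified
against finite differences in the test suite), so no deep-learning
framework is required; it runs on a single CPU at desk scale.  A
synthetic-phantom generator produces brain-like image pairs with known
smooth, fold-free ground-truth deformations and ROI labels, so the whole
pipeline is testable without any imaging data.

## Worked example

```python
import numpy as np
import symreg as sr

# a 64x64 phantom pair with a known smooth deformation (peak 3 voxels)
spec = sr.PhantomSpec(shape=(64, 64), n_rois=4, deformation_amplitude=3.0,
                      smoothness_sigma=6.0, seed=7)
pair_data = sr.make_phantom(spec)
pair = sr.PairInput.from_volumes(pair_data.template, pair_data.subject)

# unsupervised stage-1 training of the symmetric network
model = sr.build_snet(sr.NetworkConfig(spatial_dims=2, seed=0))
initial = sr.total_loss(pair.subject.data, pair.template.data,
                        sr.predict_halfway(model, pair))
cfg = sr.TrainingConfig(stage1=sr.Stage1Config(iterations_per_pair=200, lr=1e-4),
                        run_stage2=False, seed=0)
sr.train(model, [pair_data.template, pair_data.subject], cfg)

# register the pair and evaluate
result = sr.register_pair(model, pair)
final = sr.total_loss(pair.subject.data, pair.template.data, result.phi_T)
pre = np.mean((pair.subject.data - pair.template.data) ** 2)
post = np.mean((result.warped_subject.data - pair.template.data) ** 2)
report, diag = sr.evaluate_registration(result, pair_data.labels_S, pair_data.labels_T)
baseline = sr.dice(pair_data.labels_S, pair_data.labels_T).mean

print(f"total loss: {initial.total:.4f} -> {final.total:.4f}")
print(f"SSD:  {pre:.5f} -> {post:.5f}  (ratio {post / pre:.2f})")
print(f"Dice: {baseline:.3f} (unregistered) -> {report.mean:.3f}")
print(f"folds in forward field: {diag.fold_count}")
```

Output (about 10 s on one CPU core):

```
total loss: 0.0083 -> 0.0021
SSD:  0.00276 -> 0.00065  (ratio 0.24)
Dice: 0.855 (unregistered) -> 0.900
folds in forward field: 0
```

The loss falls by ~4×, the post-registration intensity mismatch drops to a
quarter of the unregistered value, ROI overlap improves over the zero-field
baseline, and the recovered forward deformation contains no folds — i.e.
the unsupervised pipeline recovers a topology-preserving approximation of
the known deformation.

## Command-line interface

`symreg` installs a console tool with subcommands `make-phantoms`, `train`,
`register`, `warp`, and `evaluate`, operating on NIfTI volumes; fields are
saved as 4-D NIfTI with a JSON sidecar recording units (voxels) and the
composition convention.  Run `symreg --help` for options; training options
(loss weights, schedules) can be given as a YAML config file.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the phantom-recovery experiment from scratch with the given
seed — phantom synthesis, stage-1 unsupervised training, registration, and
evaluation — and prints the measured loss decrease, SSD reduction, Dice
against the unregistered baseline, and the forward-field fold count.

## Documentation

`docs/methods.md` describes the model, the numerical conventions
(composition/inversion, interpolation tie-breaks, loss normalizations),
the synthetic-data generator and its limitations, and the design decisions
taken where the underlying method leaves choices open.
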