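"""Two-stage unsupervised training and pairwise registration.

Stage 1 pretrains on a small pairing plan — one image fixed as template
against every image in the cohort — with a fine-grained loop of gradient
steps per pair (default 200 at learning rate 1e-4).  Stage 2 then trains on
every ordered (template, subject) pair (self-pairs included: with n images
that is n*n pairs) for a number of epochs at a lower rate (default 1e-5)
that halves every two epochs.  Both stages use Adam on the six-term loss;
pair order in stage 2 is reshuffled every epoch from the run seed.

Batch size is 1 throughout (pairwise registration of full volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_algebra import FieldDiagnostics, field_diagnostics, negate
from .grids import DisplacementField, Volume
from .losses import LossBreakdown, LossWeights, total_loss_and_grad
from .model import PairInput, SNet, compose_full_deformations, predict_halfway
from .nn import Adam
from .warp import warp

__all__ = [
    "Stage1Config",
    "Stage2Config",
    "TrainingConfig",
    "PairingPlan",
    "RegistrationResult",
    "TrainingDivergedError",
    "make_pairing_plan",
    "stage2_learning_rate",
    "train",
    "register_pair",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""


@dataclass
class Stage1Config:
    """One-template-vs-all pretraining stage."""

    iterations_per_pair: int = 200
    lr: float = 1e-4

    def __post_init__(self):
        if self.iterations_per_pair < 0:
            raise ValueError("iterations_per_pair must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class Stage2Config:
    """All-ordered-pairs stage with a stepped learning-rate decay."""

    epochs: int = 20
    lr: float = 1e-5
    lr_decay: float = 0.5
    decay_every: int = 2
    include_self_pairs: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.decay_every < 1:
            raise ValueError("decay_every must be >= 1")


@dataclass
class TrainingConfig:
    stage1: Stage1Config = dc_field(default_factory=Stage1Config)
    stage2: Stage2Config = dc_field(default_factory=Stage2Config)
    loss_weights: LossWeights = dc_field(default_factory=LossWeights)
    seed: int = 0
    run_stage2: bool = True
    #: fixed small iteration count for the end-space inversions during
    #: training (bounds cost; inference uses full-tolerance inversion)
    invert_iters_train: int = 5
    include_endspace_losses: bool = True


@dataclass
class PairingPlan:
    """Ordered (template_id, subject_id) pairs for one stage."""

    pairs: list

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def make_pairing_plan(ids, stage: int, template_id=None,
                      include_self_pairs: bool = True) -> PairingPlan:
    """Build the pairing plan for one training (or testing) stage.

    Stage 1: ``(template_id, s)`` for every id ``s`` (n pairs, the fixed
    template also paired with itself).  Stage 2: all ordered pairs — n*n
    with self-pairs (the training-cohort counting, e.g. 30 -> 900), or
    n*(n-1) with ``include_self_pairs=False`` (the held-out testing
    counting, e.g. 10 -> 90).
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if stage == 1:
        if template_id is None:
            template_id = ids[0]
        if template_id not in ids:
            raise ValueError(f"unknown template_id {template_id!r}")
        return PairingPlan([(template_id, s) for s in ids])
    if stage == 2:
        return PairingPlan(
            [(t, s) for t in ids for s in ids if include_self_pairs or t != s]
        )
    raise ValueError("stage must be 1 or 2")


def stage2_learning_rate(cfg: Stage2Config, epoch: int) -> float:
    """Effective stage-2 rate at a (0-based) epoch: decays stepwise."""
    return cfg.lr * cfg.lr_decay ** (epoch // cfg.decay_every)


@dataclass
class TrainingHistory:
    """Per-step loss records: (stage, epoch, pair, step, LossBreakdown)."""

    records: list = dc_field(default_factory=list)

    def totals(self) -> np.ndarray:
        return np.array([r[-1].total for r in self.records])

    def __len__(self):
        return len(self.records)


def _training_step(model: SNet, optimizer: Adam, pair: PairInput,
                   cfg: TrainingConfig, lr: float) -> LossBreakdown:
    x = pair.stacked()
    phi = model.forward(x, keep_cache=True)
    breakdown, g_phi = total_loss_and_grad(
        pair.subject.data,
        pair.template.data,
        phi,
        weights=cfg.loss_weights,
        invert_max_iter=cfg.invert_iters_train,
        include_endspaces=cfg.include_endspace_losses,
    )
    if not np.isfinite(breakdown.total):
        raise TrainingDivergedError(f"non-finite loss at step: {breakdown}")
    grads = model.backward(g_phi)
    optimizer.step(grads, lr=lr)
    return breakdown


def train(model: SNet, dataset, cfg: TrainingConfig = None,
          template_id: int = 0) -> TrainingHistory:
    """Run stage 1 then (optionally) stage 2 on a cohort of volumes.

    ``dataset`` is a sequence of :class:`Volume` (or bare arrays) sharing
    one grid; pairs are formed by index.  Intensities are min–max
    normalized per volume when the pair inputs are assembled.  Returns the
    per-step loss history; the model is updated in place.  A non-finite
    loss aborts with :class:`TrainingDivergedError` naming the step.
    """
    if cfg is None:
        cfg = TrainingConfig()
    volumes = [v if isinstance(v, Volume) else Volume(np.asarray(v)) for v in dataset]
    ids = list(range(len(volumes)))
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.params)
    history = TrainingHistory()

    def pair_input(t, s):
        return PairInput.from_volumes(volumes[t], volumes[s])

    plan1 = make_pairing_plan(ids, stage=1, template_id=template_id)
    for t, s in plan1:
        pair = pair_input(t, s)
        for step in range(cfg.stage1.iterations_per_pair):
            try:
                bd = _training_step(model, optimizer, pair, cfg, cfg.stage1.lr)
            except TrainingDivergedError as exc:
                raise TrainingDivergedError(
                    f"stage 1, pair ({t},{s}), step {step}: {exc}"
                ) from None
            history.records.append((1, 0, (t, s), step, bd))

    if cfg.run_stage2 and cfg.stage2.epochs > 0:
        plan2 = make_pairing_plan(
            ids, stage=2, include_self_pairs=cfg.stage2.include_self_pairs
        )
        for epoch in range(cfg.stage2.epochs):
            lr = stage2_learning_rate(cfg.stage2, epoch)
            order = rng.permutation(len(plan2))
            for k in order:
                t, s = plan2.pairs[k]
                try:
                    bd = _training_step(model, optimizer, pair_input(t, s), cfg, lr)
                except TrainingDivergedError as exc:
                    raise TrainingDivergedError(
                        f"stage 2, epoch {epoch}, pair ({t},{s}): {exc}"
                    ) from None
                history.records.append((2, epoch, (t, s), 0, bd))
    return history


@dataclass
class RegistrationResult:
    """Everything one registered pair produces.

    ``forward`` warps the subject into template space; ``backward`` the
    template into subject space; the ``mid_*`` volumes are the two images
    met halfway in the pseudomean space.  ``diagnostics`` audits the forward
    field (Jacobian determinant extrema and interior fold count).
    """

    phi_T: DisplacementField
    phi_S: DisplacementField
    forward: DisplacementField
    backward: DisplacementField
    warped_subject: Volume
    warped_template: Volume
    mid_warped_subject: Volume
    mid_warped_template: Volume
    diagnostics: FieldDiagnostics


def register_pair(model: SNet, pair: PairInput,
                  invert_max_iter: int = 30, invert_tol: float = 1e-3
                  ) -> RegistrationResult:
    """Predict the symmetric deformations for one (possibly unseen) pair."""
    phi_T = predict_halfway(model, pair)
    phi_S = negate(phi_T)
    forward, backward = compose_full_deformations(
        phi_T, max_iter=invert_max_iter, tol=invert_tol
    )
    return RegistrationResult(
        phi_T=phi_T,
        phi_S=phi_S,
        forward=forward,
        backward=backward,
        warped_subject=warp(pair.subject, forward),
        warped_template=warp(pair.template, backward),
        mid_warped_subject=warp(pair.subject, phi_S),
        mid_warped_template=warp(pair.template, phi_T),
        diagnostics=field_diagnostics(forward),
    )
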