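"""Pairing plans, schedules, and the unsupervised training loop."""

import numpy as np
import pytest

from symreg.model import NetworkConfig, PairInput, build_snet, predict_halfway
from symreg.phantoms import PhantomSpec, make_phantom
from symreg.training import (
    Stage1Config,
    Stage2Config,
    TrainingConfig,
    make_pairing_plan,
    register_pair,
    stage2_learning_rate,
    train,
)


def tiny_model(dims=2):
    return build_snet(NetworkConfig(spatial_dims=dims, enc_channels=(4, 8),
                                    dec_channels=(8, 8, 4), seed=0))


def quick_cfg(steps, **kw):
    kw.setdefault("run_stage2", False)
    return TrainingConfig(stage1=Stage1Config(iterations_per_pair=steps, lr=1e-4), **kw)


class TestPairingPlans:
    def test_stage1_one_template_vs_all(self):
        plan = make_pairing_plan(range(30), stage=1, template_id=0)
        assert len(plan) == 30
        assert all(t == 0 for t, _ in plan)

    def test_stage2_all_ordered_pairs(self):
        assert len(make_pairing_plan(range(30), stage=2)) == 900

    def test_stage2_leave_self_out(self):
        plan = make_pairing_plan(range(10), stage=2, include_self_pairs=False)
        assert len(plan) == 90
        assert all(t != s for t, s in plan)

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            make_pairing_plan([1, 2, 3], stage=1, template_id=9)


class TestSchedules:
    def test_stage2_lr_decay_closed_form(self):
        cfg = Stage2Config(lr=1e-5, lr_decay=0.5, decay_every=2)
        assert stage2_learning_rate(cfg, 0) == 1e-5
        assert stage2_learning_rate(cfg, 1) == 1e-5
        assert stage2_learning_rate(cfg, 4) == pytest.approx(2.5e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            Stage1Config(lr=0.0)
        with pytest.raises(ValueError):
            Stage2Config(lr_decay=0.0)


@pytest.fixture(scope="module")
def phantom():
    return make_phantom(PhantomSpec(shape=(32, 32), n_rois=3,
                                    deformation_amplitude=2.0,
                                    smoothness_sigma=4.0, seed=5))


class TestTrainLoop:
    def test_zero_steps_is_a_no_op(self, phantom):
        model = tiny_model()
        before = {k: v.copy() for k, v in model.params.items()}
        history = train(model, [phantom.template, phantom.subject], quick_cfg(0))
        assert len(history) == 0
        for k, v in model.params.items():
            assert np.array_equal(v, before[k])

    def test_training_reduces_the_loss(self, phantom):
        model = tiny_model()
        history = train(model, [phantom.template, phantom.subject], quick_cfg(30))
        totals = history.totals()
        assert len(totals) == 60  # 30 steps on each of (0,0) and (0,1)
        pair_totals = totals[30:]  # the template/subject pair
        assert pair_totals[-1] < pair_totals[0]

    def test_fixed_seed_reproducibility(self, phantom):
        runs = []
        for _ in range(2):
            model = tiny_model()
            cfg = quick_cfg(5, seed=3, run_stage2=True)
            cfg.stage2 = Stage2Config(epochs=1, lr=1e-5)
            history = train(model, [phantom.template, phantom.subject], cfg)
            runs.append(history.totals())
        assert np.array_equal(runs[0], runs[1])

    def test_stage2_runs_all_ordered_pairs_per_epoch(self, phantom):
        model = tiny_model()
        cfg = TrainingConfig(stage1=Stage1Config(iterations_per_pair=0),
                             stage2=Stage2Config(epochs=2, lr=1e-5), seed=0)
        history = train(model, [phantom.template, phantom.subject], cfg)
        assert len(history) == 2 * 4  # 2 epochs x 2*2 ordered pairs

    def test_register_pair_contract(self, phantom):
        model = tiny_model()
        pair = PairInput.from_volumes(phantom.template, phantom.subject)
        result = register_pair(model, pair)
        assert np.array_equal(result.phi_S.vectors, -result.phi_T.vectors)
        assert result.forward.shape == (32, 32)
        assert result.warped_subject.shape == (32, 32)
        assert result.diagnostics.fold_count >= 0

    def test_identical_pair_post_warp_ssd_not_worse(self, phantom):
        model = tiny_model()
        pair = PairInput.from_volumes(phantom.template, phantom.template)
        pre = float(np.mean((pair.subject.data - pair.template.data) ** 2))
        result = register_pair(model, pair)
        post = float(np.mean((result.warped_subject.data - pair.template.data) ** 2))
        assert post <= pre + 1e-9

    def test_predict_halfway_matches_register_pair(self, phantom):
        model = tiny_model()
        pair = PairInput.from_volumes(phantom.template, phantom.subject)
        phi = predict_halfway(model, pair)
        result = register_pair(model, pair)
        assert np.array_equal(phi.vectors, result.phi_T.vectors)
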