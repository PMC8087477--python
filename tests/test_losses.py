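"""The six loss terms: closed forms, loop-oracle agreement, recomposition."""

import numpy as np
import pytest

from conftest import smooth_random_field
from _oracles import (
    antifold_loss_oracle,
    laplace_loss_oracle,
    ssd_oracle,
    warp_loop_oracle,
    zero_loss_oracle,
)

from symreg.field_algebra import compose, invert, negate
from symreg.grids import DisplacementField
from symreg.losses import (
    LossWeights,
    antifold_loss,
    laplace_loss,
    sim_endspaces,
    sim_sym,
    total_loss,
    zero_loss,
)


class TestSimSym:
    def test_identical_images_identity_field(self, rng):
        img = rng.random((8, 8))
        assert sim_sym(img, img, np.zeros((2, 8, 8))) == 0.0

    def test_constant_offset_closed_form(self, rng):
        img = rng.random((8, 8, 8))
        c = 0.37
        assert sim_sym(img + c, img, np.zeros((3, 8, 8, 8))) == pytest.approx(
            c**2, rel=1e-12
        )

    def test_matches_loop_oracle(self, rng):
        IS, IT = rng.random((8, 9)), rng.random((8, 9))
        v = 2.0 * rng.standard_normal((2, 8, 9))
        expected = ssd_oracle(warp_loop_oracle(IS, -v), warp_loop_oracle(IT, v))
        assert sim_sym(IS, IT, v) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            sim_sym(rng.random((8, 8)), rng.random((8, 9)), np.zeros((2, 8, 8)))


class TestSimEndspaces:
    def test_zero_field_identical_images(self, rng):
        img = rng.random((8, 8))
        assert sim_endspaces(img, img, np.zeros((2, 8, 8))) == (0.0, 0.0)

    def test_constant_offset_closed_form(self, rng):
        img = rng.random((8, 8))
        c = 0.21
        s2t, t2s = sim_endspaces(img + c, img, np.zeros((2, 8, 8)))
        assert s2t == pytest.approx(c**2, rel=1e-12)
        assert t2s == pytest.approx(c**2, rel=1e-12)

    def test_matches_explicit_two_step_oracle(self, rng):
        IS, IT = rng.random((12, 12)), rng.random((12, 12))
        phi = smooth_random_field((12, 12), 2.0, 3.0, seed=8)
        s2t, t2s = sim_endspaces(IS, IT, phi)
        # explicit invert -> explicit compose -> loop warp -> loop SSD
        fwd = compose(negate(phi), invert(phi))
        bwd = compose(phi, invert(negate(phi)))
        exp_s2t = ssd_oracle(warp_loop_oracle(IS, fwd.vectors), IT)
        exp_t2s = ssd_oracle(warp_loop_oracle(IT, bwd.vectors), IS)
        assert s2t == pytest.approx(exp_s2t, abs=1e-5)
        assert t2s == pytest.approx(exp_t2s, abs=1e-5)


class TestRegularizers:
    def test_laplace_vanishes_on_affine_fields(self):
        x = np.arange(10, dtype=float)
        v = np.zeros((2, 10, 10))
        v[0] = 0.7 * x[:, None] - 0.2 * x[None, :] + 3.0
        v[1] = -1.1 * x[None, :] + 0.5
        assert laplace_loss(v) == pytest.approx(0.0, abs=1e-20)

    def test_laplace_quadratic_hand_value(self):
        # phi_x = x**2 varying along x only: interior Laplacian = 2,
        # squared = 4 at every interior voxel, mean = 4.
        v = np.zeros((2, 8, 8))
        v[0] = (np.arange(8, dtype=float) ** 2)[:, None]
        assert laplace_loss(v) == pytest.approx(4.0, rel=1e-12)

    def test_laplace_matches_loop_oracle(self, rng):
        v = rng.standard_normal((3, 6, 7, 5))
        assert laplace_loss(v) == pytest.approx(laplace_loss_oracle(v), abs=1e-10)

    def test_zero_loss_closed_forms(self, rng):
        assert zero_loss(np.zeros((3, 8, 8, 8))) == 0.0
        v = np.zeros((3, 8, 8, 8))
        v[0], v[1], v[2] = 1.0, 2.0, 2.0
        assert zero_loss(v) == pytest.approx(9.0, rel=1e-12)
        w = rng.standard_normal((2, 7, 9))
        assert zero_loss(w) == pytest.approx(zero_loss_oracle(w), abs=1e-10)

    def test_antifold_zero_for_gentle_fields(self):
        assert antifold_loss(np.zeros((2, 8, 8))) == 0.0
        phi = smooth_random_field((12, 12), 0.4, 3.0, seed=2)
        g = np.diff(phi.vectors[0], axis=0)
        assert np.all(np.abs(g) < 0.5)  # premise of the closed form
        assert antifold_loss(phi.vectors) == 0.0

    @pytest.mark.parametrize("shape", [(8, 8), (8, 8, 8)])
    def test_antifold_contracting_field_hand_value(self, shape):
        # phi_x = -1.5 x: forward diff = -1.5, Q = -0.5, penalty 0.5 at the
        # (n-1) positions with a forward neighbour, summed then / n**D.
        D = len(shape)
        v = np.zeros((D,) + shape)
        n = shape[0]
        v[0] = (-1.5 * np.arange(n, dtype=float)).reshape((n,) + (1,) * (D - 1))
        expected = 0.5 * (n - 1) * n ** (D - 1) / n**D
        assert antifold_loss(v) == pytest.approx(expected, rel=1e-12)
        assert antifold_loss(v) == pytest.approx(antifold_loss_oracle(v), rel=1e-12)

    def test_antifold_matches_loop_oracle(self, rng):
        v = 2.0 * rng.standard_normal((2, 9, 8))
        assert antifold_loss(v) == pytest.approx(antifold_loss_oracle(v), abs=1e-10)


class TestTotalLoss:
    def test_identical_pair_identity_field_is_all_zero(self, rng):
        img = rng.random((8, 8))
        bd = total_loss(img, img, np.zeros((2, 8, 8)))
        assert bd.total == 0.0
        assert (bd.sim_sym, bd.sim_s_to_t, bd.sim_t_to_s) == (0.0, 0.0, 0.0)
        assert (bd.laplace, bd.zero, bd.antifold) == (0.0, 0.0, 0.0)

    def test_default_weights_match_reference_configuration(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.gamma) == (1.0, 0.01, 100.0)

    def test_recomposes_from_terms(self, rng):
        IS, IT = rng.random((12, 12)), rng.random((12, 12))
        phi = smooth_random_field((12, 12), 2.0, 4.0, seed=3)
        w = LossWeights(alpha=1.0, beta=0.01, gamma=100.0)
        bd = total_loss(IS, IT, phi, w)
        manual = (
            bd.sim_sym + bd.sim_s_to_t + bd.sim_t_to_s
            + w.alpha * bd.laplace + w.beta * bd.zero + w.gamma * bd.antifold
        )
        assert bd.total == pytest.approx(manual, abs=1e-10)

    def test_linear_in_each_weight(self, rng):
        IS, IT = rng.random((8, 8)), rng.random((8, 8))
        phi = smooth_random_field((8, 8), 1.5, 2.0, seed=9)
        base = total_loss(IS, IT, phi, LossWeights(1.0, 0.01, 100.0))
        doubled = total_loss(IS, IT, phi, LossWeights(2.0, 0.01, 100.0))
        assert doubled.total - base.total == pytest.approx(base.laplace, abs=1e-12)

    def test_all_terms_non_negative(self, rng):
        IS, IT = rng.random((8, 8)), rng.random((8, 8))
        phi = 3.0 * rng.standard_normal((2, 8, 8))
        bd = total_loss(IS, IT, phi)
        for term in (bd.sim_sym, bd.sim_s_to_t, bd.sim_t_to_s,
                     bd.laplace, bd.zero, bd.antifold, bd.total):
            assert term >= 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)
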