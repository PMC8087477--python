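"""Displacement-field algebra: negation, composition, inversion, Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import interior, smooth_random_field
from _oracles import forward_diff_oracle, jacobian_det_oracle

from symreg.field_algebra import (
    compose,
    count_folds,
    field_diagnostics,
    invert,
    jacobian_determinant,
    negate,
    spatial_gradient,
)
from symreg.grids import DisplacementField


def constant_field(shape, t):
    v = np.zeros((len(shape),) + tuple(shape))
    for c, tc in enumerate(t):
        v[c] = tc
    return DisplacementField(v)


class TestNegate:
    def test_zero_is_fixed_point(self):
        z = DisplacementField.zeros((6, 6))
        assert np.array_equal(negate(z).vectors, z.vectors)

    def test_constant_sign_flip(self):
        phi = constant_field((6, 6, 6), (2.0, 0.0, 0.0))
        assert np.all(negate(phi).vectors[0] == -2.0)
        assert np.all(negate(phi).vectors[1:] == 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_involution_bit_exact(self, seed):
        v = np.random.default_rng(seed).standard_normal((2, 5, 7))
        phi = DisplacementField(v)
        assert np.array_equal(negate(negate(phi)).vectors, v)


class TestCompose:
    def test_outer_identity_leaves_inner(self, rng):
        phi = smooth_random_field((12, 12), 2.0, 3.0, seed=0)
        zero = DisplacementField.zeros((12, 12))
        c = compose(zero, phi)
        assert np.allclose(c.vectors, phi.vectors, atol=1e-12)

    @pytest.mark.parametrize("t1,t2", [((1.0, 0.5), (0.25, -0.75)),
                                       ((2.0, -1.0), (-0.5, 1.5))])
    def test_translations_add_and_commute(self, t1, t2):
        shape = (16, 16)
        f1, f2 = constant_field(shape, t1), constant_field(shape, t2)
        margin = int(np.ceil(max(np.abs(t1) + np.abs(t2))))
        c12, c21 = compose(f1, f2), compose(f2, f1)
        expected = np.array(t1) + np.array(t2)
        for c in (c12, c21):
            for d in range(2):
                assert np.allclose(interior(c.vectors[d], margin), expected[d],
                                   atol=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            compose(DisplacementField.zeros((8, 8)),
                    DisplacementField.zeros((8, 10)))


class TestInvert:
    def test_zero_is_self_inverse(self):
        psi = invert(DisplacementField.zeros((8, 8)))
        assert np.all(psi.vectors == 0.0)
        assert psi.converged

    def test_constant_translation_inverse(self):
        phi = constant_field((16, 16, 16), (1.5, -0.5, 1.0))
        psi = invert(phi, max_iter=30, tol=1e-8)
        for c, t in enumerate((1.5, -0.5, 1.0)):
            assert np.allclose(interior(psi.vectors[c], 3), -t, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_smooth_field_composition_residual(self, seed):
        phi = smooth_random_field((16, 16, 16), 3.0, 6.0, seed=seed)
        psi = invert(phi, max_iter=30, tol=1e-3)
        assert psi.converged
        res = compose(phi, psi)
        mag = np.sqrt((res.vectors**2).sum(axis=0))
        assert interior(mag, 1).max() < 0.1

    def test_non_convergence_is_flagged_not_raised(self):
        phi = smooth_random_field((12, 12), 3.0, 3.0, seed=4)
        psi = invert(phi, max_iter=1, tol=1e-12)
        assert psi.converged is False

    def test_invalid_arguments(self):
        z = DisplacementField.zeros((8, 8))
        with pytest.raises(ValueError):
            invert(z, max_iter=0)
        with pytest.raises(ValueError):
            invert(z, tol=0.0)


class TestJacobianDeterminant:
    def test_identity_map_everywhere_one(self):
        det = jacobian_determinant(DisplacementField.zeros((8, 8, 8)))
        assert np.array_equal(det.data, np.ones((8, 8, 8)))

    @pytest.mark.parametrize("a", [0.25, -0.4])
    def test_linear_map_closed_form(self, a):
        shape = (10, 10)
        v = np.zeros((2,) + shape)
        v[0] = a * np.arange(10)[:, None]
        det = jacobian_determinant(DisplacementField(v))
        assert np.allclose(det.data, 1.0 + a, atol=1e-12)

    @pytest.mark.parametrize("shape", [(8, 8), (8, 8, 8)])
    def test_matches_per_voxel_determinant_oracle(self, shape, rng):
        v = 0.8 * rng.standard_normal((len(shape),) + shape)
        det = jacobian_determinant(DisplacementField(v))
        assert np.allclose(det.data, jacobian_det_oracle(v), atol=1e-10)


class TestCountFolds:
    def test_zero_field_has_no_folds(self):
        assert count_folds(DisplacementField.zeros((8, 8, 8))) == 0

    def test_contracting_linear_field_folds_every_interior_voxel(self):
        # phi_x = -1.5 x gives det = 1 - 1.5 = -0.5 at every voxel; the
        # count covers interior voxels only: (8-2)**3.
        v = np.zeros((3, 8, 8, 8))
        v[0] = -1.5 * np.arange(8)[:, None, None]
        assert count_folds(DisplacementField(v)) == 6**3

    def test_small_smooth_perturbation_is_fold_free(self):
        phi = smooth_random_field((16, 16, 16), 0.3, 2.0, seed=3)
        assert count_folds(phi) == 0

    def test_diagnostics_summary(self):
        phi = smooth_random_field((12, 12), 0.3, 2.0, seed=5)
        diag = field_diagnostics(phi)
        assert diag.fold_count == 0
        assert diag.min_det <= 1.0 <= diag.max_det
        assert diag.jacobian_det.shape == (12, 12)


class TestSpatialGradient:
    def test_constant_field_zero_gradient(self):
        g = spatial_gradient(constant_field((8, 8), (1.0, -2.0)))
        assert np.all(g == 0.0)

    def test_linear_field_constant_gradient(self):
        v = np.zeros((2, 8, 8))
        v[0] = 0.3 * np.arange(8)[:, None]
        g = spatial_gradient(DisplacementField(v))
        assert np.allclose(g[0, 0, :-1, :], 0.3, atol=1e-12)
        assert np.all(g[0, 1] == 0.0) and np.all(g[1] == 0.0)

    def test_matches_index_arithmetic_oracle_exactly(self, rng):
        v = rng.standard_normal((3, 5, 6, 4))
        g = spatial_gradient(DisplacementField(v))
        assert np.array_equal(g, forward_diff_oracle(v))
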