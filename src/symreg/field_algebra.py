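"""Algebra of dense displacement fields.

Fields are resolution-matched arrays of per-voxel displacement vectors in
voxel units (see :mod:`symreg.grids`).  This module provides the operations a
symmetric registration pipeline needs to turn one predicted halfway field
into full forward/backward deformations and to audit their regularity:

* ``negate`` — the subject-side halfway field is the exact negation of the
  template-side field.
* ``compose`` — chaining two deformations,
  ``compose(outer, inner)(u) = inner(u) + outer(u + inner(u))``, so that the
  deformation maps satisfy ``T_c = T_outer ∘ T_inner``; warping an image by
  the composite equals warping by ``outer`` first and then resampling that
  result by ``inner``.  (The opposite order convention exists in other
  toolkits; this one is fixed here and recorded in serialized sidecars.)
* ``invert`` — fixed-point inversion of a (fold-free) field.
* ``jacobian_determinant`` / ``count_folds`` — per-voxel determinant of the
  deformation map ``u -> u + phi(u)`` and the count of interior voxels where
  it is negative (a fold: local self-intersection of the deformation).
* ``spatial_gradient`` — forward-difference derivatives, the stencil used by
  the antifold penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._interp import sample_linear
from .grids import DisplacementField, Volume, identity_grid

__all__ = [
    "FieldDiagnostics",
    "negate",
    "compose",
    "invert",
    "jacobian_determinant",
    "count_folds",
    "spatial_gradient",
    "field_diagnostics",
    "COMPOSITION_CONVENTION",
]

#: Recorded in serialized field sidecars so downstream users know the order.
COMPOSITION_CONVENTION = "compose(outer, inner)(u) = inner(u) + outer(u + inner(u))"


@dataclass
class FieldDiagnostics:
    """Regularity summary of one displacement field."""

    jacobian_det: Volume
    fold_count: int
    min_det: float
    max_det: float


def negate(phi: DisplacementField) -> DisplacementField:
    """Sign-flip every displacement component (bit-exact involution)."""
    return DisplacementField(-phi.vectors)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Compose two displacement fields.

    Returns ``c`` with ``c(u) = inner(u) + outer(u + inner(u))``, where
    ``outer`` is resampled multilinearly with boundary clamping — the same
    interpolation as the spatial-transformer warp, so warping by ``c``
    matches the two-step warp up to interpolation error.
    """
    if outer.shape != inner.shape:
        raise ValueError(f"shape mismatch: {outer.shape} vs {inner.shape}")
    points = identity_grid(inner.shape) + inner.vectors
    return DisplacementField(inner.vectors + sample_linear(outer.vectors, points))


def invert(
    phi: DisplacementField,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> DisplacementField:
    """Approximate inverse displacement by fixed-point iteration.

    Iterates ``psi <- -phi(u + psi(u))`` from ``psi_0 = -phi`` until the
    largest per-voxel update falls below ``tol`` (voxels) or ``max_iter``
    iterations have run.  For smooth, fold-free fields with displacements of
    a few voxels this converges quickly; the returned field's ``converged``
    flag reports whether the tolerance was met (non-convergence is flagged,
    never raised).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    ident = identity_grid(phi.shape)
    psi = -phi.vectors
    converged = False
    for _ in range(max_iter):
        new = -sample_linear(phi.vectors, ident + psi)
        update = float(np.abs(new - psi).max())
        psi = new
        if update < tol:
            converged = True
            break
    return DisplacementField(psi, converged=converged)


def spatial_gradient(phi: DisplacementField) -> np.ndarray:
    """Forward-difference derivatives of each component along each axis.

    Returns an array ``g`` of shape ``(D, D, *spatial)`` with
    ``g[c, a] = phi_c(u + e_a) - phi_c(u)``.  The last slice along axis ``a``
    (where no forward neighbour exists) is set to zero.
    """
    D = phi.ndim
    g = np.zeros((D, D) + phi.shape)
    for c in range(D):
        for a in range(D):
            sl_hi = [slice(None)] * D
            sl_lo = [slice(None)] * D
            sl_hi[a] = slice(1, None)
            sl_lo[a] = slice(None, -1)
            valid = [slice(None)] * D
            valid[a] = slice(None, -1)
            g[(c, a) + tuple(valid)] = (
                phi.vectors[(c,) + tuple(sl_hi)] - phi.vectors[(c,) + tuple(sl_lo)]
            )
    return g


def jacobian_determinant(phi: DisplacementField, spacing=None) -> Volume:
    """Per-voxel determinant of the Jacobian of ``u -> u + phi(u)``.

    Derivatives are central differences in the interior and one-sided at the
    boundary.  The identity field yields 1 everywhere; negative values mark
    folds.  With anisotropic ``spacing`` the derivative of component ``c``
    along axis ``a`` is scaled by ``spacing[c]/spacing[a]`` (all test data
    are isotropic, where this is a no-op).
    """
    D = phi.ndim
    J = np.empty(phi.shape + (D, D))
    for c in range(D):
        grads = np.gradient(phi.vectors[c], edge_order=1)
        if D == 1:  # np.gradient returns a bare array in 1-D
            grads = [grads]
        for a in range(D):
            g = grads[a]
            if spacing is not None:
                g = g * (spacing[c] / spacing[a])
            J[..., c, a] = g
            if c == a:
                J[..., c, a] += 1.0
    return Volume(np.linalg.det(J))


def _interior_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(slice(1, -1) for _ in shape)] = True
    return mask


def count_folds(phi: DisplacementField) -> int:
    """Number of interior voxels where the Jacobian determinant is negative.

    The one-voxel boundary shell is excluded: the one-sided stencil there
    reflects extrapolation, not the deformation's local topology.
    """
    det = jacobian_determinant(phi).data
    return int(np.count_nonzero(det[_interior_mask(det.shape)] < 0))


def field_diagnostics(phi: DisplacementField) -> FieldDiagnostics:
    """Jacobian determinant map, interior fold count, and det extrema."""
    det = jacobian_determinant(phi)
    interior = det.data[_interior_mask(det.data.shape)]
    return FieldDiagnostics(
        jacobian_det=det,
        fold_count=int(np.count_nonzero(interior < 0)),
        min_det=float(det.data.min()),
        max_det=float(det.data.max()),
    )
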