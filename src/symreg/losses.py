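"""The six-term unsupervised registration loss and its gradient.

The network predicts a single halfway field ``phi_T``; the subject-side
field is its negation ``phi_S = -phi_T``.  The total training loss is

    L = L_sim_sym + L_sim_{S->T} + L_sim_{T->S}
        + alpha * L_laplace + beta * L_zero + gamma * L_antifold

with defaults ``alpha = 1``, ``beta = 0.01``, ``gamma = 100``.

Similarity terms are mean squared intensity differences (SSD normalized by
voxel count, so the printed weights remain meaningful across resolutions):

* ``sim_sym`` compares the two images pulled into the pseudomean space,
  ``warp(I_S, -phi_T)`` vs ``warp(I_T, phi_T)``.
* ``sim_endspaces`` compares in the two end spaces, using the composed full
  deformations: the subject warped into template space against ``I_T``, and
  the template warped into subject space against ``I_S``.  The inverse
  fields come from fixed-point inversion; during training a small iteration
  count bounds the cost and the inverse is treated as a stopped-gradient
  input (gradients flow through the directly resampled operand).

Regularizers act on ``phi_T`` only (``phi_S`` inherits its smoothness):

* ``laplace_loss`` — squared discrete Laplacian (second central differences
  summed over axes), summed over components, averaged over interior voxels.
* ``zero_loss`` — mean squared displacement magnitude, discouraging
  needlessly large deformations.
* ``antifold_loss`` — penalizes same-axis forward differences whose value
  ``d(phi_d)/d(d) + 1`` (the diagonal Jacobian entry of the deformation
  map) drops to 0 or below: ``R(Q) = |Q|`` for ``Q <= 0`` else 0, summed and
  normalized by voxel count.

Intensities are expected to be min–max normalized to [0, 1] *before* these
losses are evaluated (the training pipeline does this once per pair); the
loss functions themselves do not rescale their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .field_algebra import compose, invert, negate
from .grids import DisplacementField, Volume, identity_grid
from ._interp import sample_linear, sample_linear_adjoint
from .warp import warp_array, warp_with_grad

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "sim_sym",
    "sim_endspaces",
    "laplace_loss",
    "zero_loss",
    "antifold_loss",
    "total_loss",
    "total_loss_and_grad",
]


@dataclass
class LossWeights:
    """Balance coefficients of the regularization terms."""

    alpha: float = 1.0
    beta: float = 0.01
    gamma: float = 100.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    """All six loss terms and their weighted total."""

    sim_sym: float
    sim_s_to_t: float
    sim_t_to_s: float
    laplace: float
    zero: float
    antifold: float
    total: float

    def __str__(self):  # compact one-line form for logs
        return (
            f"total={self.total:.6g} sym={self.sim_sym:.4g} "
            f"s2t={self.sim_s_to_t:.4g} t2s={self.sim_t_to_s:.4g} "
            f"lap={self.laplace:.4g} zero={self.zero:.4g} anti={self.antifold:.4g}"
        )


def _data(x):
    return x.data if isinstance(x, Volume) else np.asarray(x, dtype=float)


def _vec(phi):
    return phi.vectors if isinstance(phi, DisplacementField) else np.asarray(phi, float)


def _check_shapes(I_S, I_T, phi):
    if _data(I_S).shape != _data(I_T).shape or _data(I_S).shape != _vec(phi).shape[1:]:
        raise ValueError(
            f"shape mismatch: subject {_data(I_S).shape}, template {_data(I_T).shape}, "
            f"field {_vec(phi).shape[1:]}"
        )


# ---------------------------------------------------------------------------
# similarity terms


def sim_sym(I_S, I_T, phi_T) -> float:
    """Pseudomean-space symmetric similarity (mean squared difference)."""
    _check_shapes(I_S, I_T, phi_T)
    v = _vec(phi_T)
    a = warp_array(_data(I_S), -v)
    b = warp_array(_data(I_T), v)
    return float(np.mean((a - b) ** 2))


def full_deformations(phi_T, max_iter: int = 30, tol: float = 1e-3):
    """Forward and backward composed fields from the halfway field.

    forward  = compose(phi_S, invert(phi_T))  — warps the subject image into
               template space (the subject→template pathway);
    backward = compose(phi_T, invert(phi_S))  — warps the template image into
               subject space.  ``phi_S = -phi_T`` throughout.
    """
    phi_T = phi_T if isinstance(phi_T, DisplacementField) else DisplacementField(phi_T)
    phi_S = negate(phi_T)
    inv_T = invert(phi_T, max_iter=max_iter, tol=tol)
    inv_S = invert(phi_S, max_iter=max_iter, tol=tol)
    forward = compose(phi_S, inv_T)
    backward = compose(phi_T, inv_S)
    forward.converged = inv_T.converged
    backward.converged = inv_S.converged
    return forward, backward


def sim_endspaces(I_S, I_T, phi_T, invert_max_iter: int = 30, invert_tol: float = 1e-3):
    """End-space similarity pair ``(L_{S->T}, L_{T->S})``.

    ``L_{S->T}`` is the mean squared difference between the subject warped
    all the way into template space and the template, and symmetrically for
    ``L_{T->S}``.  Inversion non-convergence is flagged on the composed
    fields, not raised.
    """
    _check_shapes(I_S, I_T, phi_T)
    forward, backward = full_deformations(
        phi_T, max_iter=invert_max_iter, tol=invert_tol
    )
    s2t = float(np.mean((warp_array(_data(I_S), forward.vectors) - _data(I_T)) ** 2))
    t2s = float(np.mean((warp_array(_data(I_T), backward.vectors) - _data(I_S)) ** 2))
    return s2t, t2s


# ---------------------------------------------------------------------------
# regularizers


_LAP_KERNEL = np.array([1.0, -2.0, 1.0])


def _laplacian(component: np.ndarray) -> np.ndarray:
    """Sum of second central differences over axes, zero-padded boundaries."""
    out = np.zeros_like(component)
    for a in range(component.ndim):
        out += correlate1d(component, _LAP_KERNEL, axis=a, mode="constant", cval=0.0)
    return out


def _interior_mask(shape):
    m = np.zeros(shape, dtype=bool)
    m[tuple(slice(1, -1) for _ in shape)] = True
    return m


def laplace_loss(phi_T) -> float:
    """Mean over interior voxels of the squared Laplacian vector norm.

    Zero for every affine field (second differences of affine maps vanish).
    """
    v = _vec(phi_T)
    mask = _interior_mask(v.shape[1:])
    total = 0.0
    for c in range(v.shape[0]):
        lap = _laplacian(v[c])
        total += float((lap[mask] ** 2).sum())
    return total / mask.sum()


def zero_loss(phi_T) -> float:
    """Mean squared displacement vector norm, ``mean_u ||phi(u)||^2``."""
    v = _vec(phi_T)
    return float((v**2).sum() / v[0].size)


def _forward_diff(component: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference along ``axis``; zero on the final slice."""
    out = np.zeros_like(component)
    sl_valid = [slice(None)] * component.ndim
    sl_valid[axis] = slice(None, -1)
    sl_hi = [slice(None)] * component.ndim
    sl_hi[axis] = slice(1, None)
    out[tuple(sl_valid)] = component[tuple(sl_hi)] - component[tuple(sl_valid)]
    return out


def antifold_loss(phi_T) -> float:
    """Penalty on non-positive diagonal Jacobian entries of the deformation.

    For each axis ``d``, ``Q = d(phi_d)/d(d) + 1`` (forward differences);
    the ramp ``R(Q) = |Q|`` for ``Q <= 0`` and 0 otherwise is summed over
    voxels and axes and normalized by voxel count.  Exactly zero whenever
    every same-axis derivative exceeds -1.
    """
    v = _vec(phi_T)
    n = v[0].size
    total = 0.0
    for d in range(v.shape[0]):
        q = _forward_diff(v[d], d) + 1.0
        total += float(np.abs(q[q <= 0]).sum())
    return total / n


# ---------------------------------------------------------------------------
# total


def total_loss(I_S, I_T, phi_T, weights: LossWeights = None,
               invert_max_iter: int = 30, invert_tol: float = 1e-3) -> LossBreakdown:
    """Evaluate all six terms and their weighted sum."""
    if weights is None:
        weights = LossWeights()
    _check_shapes(I_S, I_T, phi_T)
    s_sym = sim_sym(I_S, I_T, phi_T)
    s2t, t2s = sim_endspaces(I_S, I_T, phi_T, invert_max_iter, invert_tol)
    lap = laplace_loss(phi_T)
    zer = zero_loss(phi_T)
    anti = antifold_loss(phi_T)
    total = (
        s_sym + s2t + t2s
        + weights.alpha * lap + weights.beta * zer + weights.gamma * anti
    )
    return LossBreakdown(s_sym, s2t, t2s, lap, zer, anti, total)


def total_loss_and_grad(
    I_S,
    I_T,
    phi_T,
    weights: LossWeights = None,
    invert_max_iter: int = 5,
    invert_tol: float = 1e-3,
    include_endspaces: bool = True,
) -> tuple:
    """Loss breakdown and the gradient of the total w.r.t. ``phi_T``.

    The training path.  The end-space terms treat the fixed-point inverse
    fields as stopped-gradient inputs: gradients flow through the operand
    that is resampled directly (the halfway field inside the composition and
    the image inside the warp), not through the inversion iterations.  The
    default ``invert_max_iter=5`` bounds the per-step cost; evaluation-time
    code uses the full-tolerance inversion instead.
    """
    if weights is None:
        weights = LossWeights()
    _check_shapes(I_S, I_T, phi_T)
    IS, IT, v = _data(I_S), _data(I_T), _vec(phi_T)
    D = v.shape[0]
    n = v[0].size
    grad = np.zeros_like(v)

    # --- pseudomean symmetric SSD
    a, ga = warp_with_grad(IS, -v)   # ga[c] = d a / d(sample coord c)
    b, gb = warp_with_grad(IT, v)
    r = a - b
    s_sym = float(np.mean(r**2))
    # d a/d v_c = -ga_c (subject is warped by -phi), d b/d v_c = +gb_c
    grad += (2.0 / n) * r * (-ga - gb)

    # --- end-space SSDs
    s2t = t2s = 0.0
    if include_endspaces:
        ident = identity_grid(v.shape[1:])
        inv_T = invert(DisplacementField(v), max_iter=invert_max_iter, tol=invert_tol)
        inv_S = invert(DisplacementField(-v), max_iter=invert_max_iter, tol=invert_tol)

        # forward = inv_T + (-v) resampled at u + inv_T(u); inv_T stop-grad
        pts_f = ident + inv_T.vectors
        fwd = inv_T.vectors + sample_linear(-v, pts_f)
        wf, gwf = warp_with_grad(IS, fwd)
        rf = wf - IT
        s2t = float(np.mean(rf**2))
        gf = (2.0 / n) * rf * gwf          # dL/d(fwd_c)
        grad -= sample_linear_adjoint(gf, pts_f, v.shape[1:])

        # backward = inv_S + v resampled at u + inv_S(u); inv_S stop-grad
        pts_b = ident + inv_S.vectors
        bwd = inv_S.vectors + sample_linear(v, pts_b)
        wb, gwb = warp_with_grad(IT, bwd)
        rb = wb - IS
        t2s = float(np.mean(rb**2))
        gb2 = (2.0 / n) * rb * gwb
        grad += sample_linear_adjoint(gb2, pts_b, v.shape[1:])

    # --- Laplace smoothness (self-adjoint stencil with zero padding)
    mask = _interior_mask(v.shape[1:])
    m = mask.sum()
    lap_total = 0.0
    for c in range(D):
        lap = _laplacian(v[c])
        lap *= mask
        lap_total += float((lap**2).sum())
        grad[c] += weights.alpha * (2.0 / m) * _laplacian(lap)
    lap_loss = lap_total / m

    # --- zero constraint
    zer = float((v**2).sum() / n)
    grad += weights.beta * (2.0 / n) * v

    # --- antifold
    anti_total = 0.0
    for d in range(D):
        q = _forward_diff(v[d], d) + 1.0
        neg = q <= 0
        anti_total += float(np.abs(q[neg]).sum())
        s = np.where(q < 0, -1.0, 0.0)  # dR/dQ (subgradient 0 at the kink)
        # adjoint of the forward difference: g[i] -= s[i]; g[i+1] += s[i]
        adj = -s
        sl_hi = [slice(None)] * (v.ndim - 1)
        sl_hi[d] = slice(1, None)
        sl_lo = [slice(None)] * (v.ndim - 1)
        sl_lo[d] = slice(None, -1)
        adj[tuple(sl_hi)] += s[tuple(sl_lo)]
        grad[d] += weights.gamma * adj / n
    anti = anti_total / n

    total = (
        s_sym + s2t + t2s
        + weights.alpha * lap_loss + weights.beta * zer + weights.gamma * anti
    )
    return LossBreakdown(s_sym, s2t, t2s, lap_loss, zer, anti, total), grad
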