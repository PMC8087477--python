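"""Low-level multilinear sampling on regular grids.

Shared by the spatial-transformer warp and the field algebra (composition,
inversion).  All samplers clamp out-of-grid coordinates to the boundary
(border replication), and use the floor-based 2**D cell so that weights at
exactly-integer coordinates select the integer voxel exactly.
"""

from __future__ import annotations

import itertools

import numpy as np


def _corner_cells(points, shape):
    """Clamp sample points and split into base corner + fractional offset.

    Parameters
    ----------
    points
        Absolute voxel coordinates, shape ``(D, *out)``.
    shape
        Spatial extents of the sampled grid.

    Returns
    -------
    base : int array (D, *out) — lower corner index per axis, in [0, n-2]
    frac : float array (D, *out) — offset in [0, 1] within the cell
    inside : bool array (D, *out) — True where the (unclamped) coordinate lies
        strictly inside [0, n-1]; derivative w.r.t. the coordinate is zero
        outside because of clamping.
    """
    D = points.shape[0]
    base = np.empty(points.shape, dtype=np.intp)
    frac = np.empty_like(points, dtype=float)
    inside = np.empty(points.shape, dtype=bool)
    for c in range(D):
        n = shape[c]
        p = np.clip(points[c], 0.0, n - 1.0)
        b = np.floor(p).astype(np.intp)
        np.clip(b, 0, n - 2, out=b)
        base[c] = b
        frac[c] = p - b
        inside[c] = (points[c] > 0.0) & (points[c] < n - 1.0)
    return base, frac, inside


def sample_linear(values, points):
    """Multilinear interpolation of ``values`` at ``points``.

    ``values`` has shape ``(*spatial,)`` or ``(C, *spatial)``; ``points`` has
    shape ``(D, *out)``.  Returns shape ``(*out,)`` or ``(C, *out)``.
    """
    values = np.asarray(values)
    D = points.shape[0]
    channelled = values.ndim == D + 1
    shape = values.shape[1:] if channelled else values.shape
    base, frac, _ = _corner_cells(points, shape)

    out = 0.0
    for offsets in itertools.product((0, 1), repeat=D):
        idx = tuple(base[c] + offsets[c] for c in range(D))
        w = 1.0
        for c in range(D):
            w = w * (frac[c] if offsets[c] else (1.0 - frac[c]))
        if channelled:
            out = out + values[(slice(None),) + idx] * w
        else:
            out = out + values[idx] * w
    return out


def sample_linear_with_grad(values, points):
    """Sample and return the exact derivative w.r.t. each point coordinate.

    Returns ``(sampled, grad)`` with ``grad[c]`` = d(sampled)/d(points[c]),
    the analytic derivative of the multilinear interpolant (zero where the
    coordinate is clamped at the boundary).  ``values`` must be scalar-valued
    (shape ``(*spatial,)``).
    """
    values = np.asarray(values, dtype=float)
    D = points.shape[0]
    base, frac, inside = _corner_cells(points, values.shape)

    out = np.zeros(points.shape[1:])
    grad = np.zeros(points.shape)
    for offsets in itertools.product((0, 1), repeat=D):
        idx = tuple(base[c] + offsets[c] for c in range(D))
        v = values[idx]
        w_axes = [frac[c] if offsets[c] else (1.0 - frac[c]) for c in range(D)]
        w = np.prod(w_axes, axis=0)
        out += v * w
        for c in range(D):
            # d(weight)/d(frac_c): +1 for the high corner, -1 for the low one
            dw = 1.0 if offsets[c] else -1.0
            others = 1.0
            for c2 in range(D):
                if c2 != c:
                    others = others * w_axes[c2]
            grad[c] += v * dw * others
    grad *= inside  # clamped coordinates have zero derivative
    return out, grad


def sample_linear_adjoint(grad_out, points, shape):
    """Adjoint of ``sample_linear`` w.r.t. the sampled values.

    Scatters ``grad_out`` (shape ``(*out,)`` or ``(C, *out)``) back onto a
    grid of spatial ``shape`` with the same interpolation weights used at
    ``points``.  Returns shape ``(*shape,)`` or ``(C, *shape)``.
    """
    grad_out = np.asarray(grad_out, dtype=float)
    D = points.shape[0]
    channelled = grad_out.ndim == D + 1
    base, frac, _ = _corner_cells(points, shape)

    if channelled:
        acc = np.zeros((grad_out.shape[0],) + tuple(shape))
    else:
        acc = np.zeros(tuple(shape))
    for offsets in itertools.product((0, 1), repeat=D):
        idx = tuple(base[c] + offsets[c] for c in range(D))
        w = 1.0
        for c in range(D):
            w = w * (frac[c] if offsets[c] else (1.0 - frac[c]))
        if channelled:
            for ch in range(grad_out.shape[0]):
                np.add.at(acc[ch], idx, grad_out[ch] * w)
        else:
            np.add.at(acc, idx, grad_out * w)
    return acc


def sample_nearest(values, points):
    """Nearest-neighbour sampling with boundary clamping (for label maps)."""
    values = np.asarray(values)
    D = points.shape[0]
    idx = []
    for c in range(D):
        n = values.shape[c]
        i = np.rint(np.clip(points[c], 0.0, n - 1.0)).astype(np.intp)
        idx.append(i)
    return values[tuple(idx)]
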