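"""Independent brute-force oracles used to check the vectorized code.

Everything here is written with explicit per-voxel loops and index
arithmetic, deliberately sharing no code with the package implementation.
"""

import itertools

import numpy as np


def warp_loop_oracle(image: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Direct per-voxel multilinear interpolation with boundary clamping."""
    D = image.ndim
    out = np.zeros(image.shape, dtype=float)
    for u in np.ndindex(image.shape):
        x = []
        for d in range(D):
            xd = u[d] + vectors[(d,) + u]
            xd = min(max(xd, 0.0), image.shape[d] - 1.0)
            x.append(xd)
        base = [min(int(np.floor(xd)), image.shape[d] - 2) for d, xd in enumerate(x)]
        acc = 0.0
        for off in itertools.product((0, 1), repeat=D):
            v = tuple(base[d] + off[d] for d in range(D))
            w = 1.0
            for d in range(D):
                w *= 1.0 - abs(x[d] - v[d])
            acc += image[v] * w
        out[u] = acc
    return out


def jacobian_det_oracle(vectors: np.ndarray) -> np.ndarray:
    """Per-voxel determinant of I + grad(phi), explicit stencils and cofactors."""
    D = vectors.shape[0]
    shape = vectors.shape[1:]
    det = np.zeros(shape)
    for u in np.ndindex(shape):
        J = np.zeros((D, D))
        for c in range(D):
            for a in range(D):
                n = shape[a]
                up = list(u)
                dn = list(u)
                if 0 < u[a] < n - 1:
                    up[a] += 1
                    dn[a] -= 1
                    h = 2.0
                elif u[a] == 0:
                    up[a] += 1
                    h = 1.0
                else:
                    dn[a] -= 1
                    h = 1.0
                J[c, a] = (vectors[(c,) + tuple(up)] - vectors[(c,) + tuple(dn)]) / h
            J[c, c] += 1.0
        if D == 2:
            det[u] = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        else:
            det[u] = (
                J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
                - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
                + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
            )
    return det


def forward_diff_oracle(vectors: np.ndarray) -> np.ndarray:
    """g[c, a, u] = phi_c(u + e_a) - phi_c(u); zero where u_a = n_a - 1."""
    D = vectors.shape[0]
    shape = vectors.shape[1:]
    g = np.zeros((D, D) + shape)
    for c in range(D):
        for a in range(D):
            for u in np.ndindex(shape):
                if u[a] < shape[a] - 1:
                    up = list(u)
                    up[a] += 1
                    g[(c, a) + u] = vectors[(c,) + tuple(up)] - vectors[(c,) + u]
    return g


def laplace_loss_oracle(vectors: np.ndarray) -> float:
    """Mean over interior voxels of sum_c (sum_a second difference)^2."""
    D = vectors.shape[0]
    shape = vectors.shape[1:]
    interior = [range(1, n - 1) for n in shape]
    total, count = 0.0, 0
    for u in itertools.product(*interior):
        count += 1
        for c in range(D):
            lap = 0.0
            for a in range(D):
                up = list(u)
                dn = list(u)
                up[a] += 1
                dn[a] -= 1
                lap += (
                    vectors[(c,) + tuple(up)]
                    - 2.0 * vectors[(c,) + u]
                    + vectors[(c,) + tuple(dn)]
                )
            total += lap**2
    return total / count


def zero_loss_oracle(vectors: np.ndarray) -> float:
    shape = vectors.shape[1:]
    total = 0.0
    for u in np.ndindex(shape):
        for c in range(vectors.shape[0]):
            total += vectors[(c,) + u] ** 2
    return total / np.prod(shape)


def antifold_loss_oracle(vectors: np.ndarray) -> float:
    """Sum of R(fwd-diff + 1) over same-axis derivatives, / voxel count."""
    D = vectors.shape[0]
    shape = vectors.shape[1:]
    total = 0.0
    for d in range(D):
        for u in np.ndindex(shape):
            if u[d] == shape[d] - 1:
                continue
            up = list(u)
            up[d] += 1
            q = vectors[(d,) + tuple(up)] - vectors[(d,) + u] + 1.0
            if q <= 0:
                total += abs(q)
    return total / np.prod(shape)


def ssd_oracle(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    for u in np.ndindex(a.shape):
        total += (a[u] - b[u]) ** 2
    return total / a.size


def dice_oracle(a: np.ndarray, b: np.ndarray, roi: int) -> float:
    na = int((a == roi).sum())
    nb = int((b == roi).sum())
    inter = int(((a == roi) & (b == roi)).sum())
    return 2.0 * inter / (na + nb)
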