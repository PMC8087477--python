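"""Minimal convolutional-network machinery on numpy arrays.

No deep-learning framework is assumed: forward passes use
``sliding_window_view`` + ``einsum`` and every layer carries a hand-derived
backward pass (verified against finite differences in the test suite).
Layers operate on channel-first arrays ``(C, *spatial)`` with 2-D or 3-D
spatial grids, kernel size 3 and 'same' padding throughout — the shapes a
small registration encoder–decoder needs.  Parameters live in plain dicts of
numpy arrays so checkpointing is a single ``np.savez``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv_forward", "conv_backward", "leaky_relu", "leaky_relu_backward",
           "upsample_nearest", "upsample_nearest_backward", "Adam"]

_KSIZE = 3
_PAD = 1

# einsum subscripts per spatial dimensionality
_FWD_EINSUM = {2: "ocij,cxyij->oxy", 3: "ocijk,cxyzijk->oxyz"}
_WGT_EINSUM = {2: "oxy,cxyij->ocij", 3: "oxyz,cxyzijk->ocijk"}


def _windows(x_padded: np.ndarray, D: int, stride: int) -> np.ndarray:
    """All kernel-sized windows of a padded (C, *spatial) array, strided."""
    win = sliding_window_view(x_padded, (_KSIZE,) * D, axis=tuple(range(1, D + 1)))
    if stride > 1:
        sl = (slice(None),) + (slice(None, None, stride),) * D
        win = win[sl]
    return win


def conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 1):
    """Cross-correlation with kernel 3, padding 1, stride 1 or 2.

    ``x``: (C_in, *spatial); ``W``: (C_out, C_in, 3, ..); ``b``: (C_out,).
    Returns (y, cache) where cache is reused by :func:`conv_backward`.
    """
    D = x.ndim - 1
    pad = ((0, 0),) + ((_PAD, _PAD),) * D
    xp = np.pad(x, pad)
    win = _windows(xp, D, stride)
    y = np.einsum(_FWD_EINSUM[D], W, win, optimize=True)
    y += b.reshape((-1,) + (1,) * D)
    return y, (win, x.shape, stride)


def conv_backward(gy: np.ndarray, W: np.ndarray, cache):
    """Gradients of a conv layer: returns (gx, gW, gb)."""
    win, x_shape, stride = cache
    D = gy.ndim - 1
    gW = np.einsum(_WGT_EINSUM[D], gy, win, optimize=True)
    gb = gy.reshape(gy.shape[0], -1).sum(axis=1)

    # gx: transposed convolution = correlate the zero-dilated gy with the
    # spatially flipped kernel, channels swapped.
    spatial_in = x_shape[1:]
    if stride > 1:
        dil_shape = tuple((m - 1) * stride + 1 for m in gy.shape[1:])
        gyd = np.zeros((gy.shape[0],) + dil_shape)
        sl = (slice(None),) + (slice(None, None, stride),) * D
        gyd[sl] = gy
    else:
        gyd = gy
    # asymmetric padding restores the exact input extent (output_padding)
    pads = [(0, 0)]
    for a in range(D):
        left = _KSIZE - 1 - _PAD
        opad = spatial_in[a] - (gyd.shape[1 + a] - 2 * _PAD + _KSIZE - 1)
        pads.append((left, left + opad))
    gyp = np.pad(gyd, pads)
    flip = (slice(None), slice(None)) + (slice(None, None, -1),) * D
    Wt = np.swapaxes(W[flip], 0, 1)  # (C_in, C_out, *k)
    win_g = _windows(gyp, D, 1)
    gx = np.einsum(_FWD_EINSUM[D], Wt, win_g, optimize=True)
    return gx, gW, gb


def leaky_relu(x: np.ndarray, slope: float = 0.2):
    return np.where(x > 0, x, slope * x)


def leaky_relu_backward(gy: np.ndarray, x: np.ndarray, slope: float = 0.2):
    return gy * np.where(x > 0, 1.0, slope)


def upsample_nearest(x: np.ndarray, factor: int = 2) -> np.ndarray:
    """Repeat each voxel ``factor`` times along every spatial axis."""
    y = x
    for a in range(1, x.ndim):
        y = np.repeat(y, factor, axis=a)
    return y


def upsample_nearest_backward(gy: np.ndarray, factor: int = 2) -> np.ndarray:
    """Adjoint of nearest upsampling: sum over each factor**D block."""
    D = gy.ndim - 1
    shape = [gy.shape[0]]
    for a in range(D):
        shape.extend([gy.shape[1 + a] // factor, factor])
    g = gy.reshape(shape)
    for a in range(D):
        g = g.sum(axis=2 + a)
    return g


class Adam:
    """Adam optimizer over a dict of named numpy parameters."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, lr: float = None):
        """One update; ``lr`` overrides the stored rate (for schedules)."""
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
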