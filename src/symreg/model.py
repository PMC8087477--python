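"""The symmetric registration network.

A VoxelMorph-style fully convolutional encoder–decoder maps the stacked
(template, subject, difference-map) grid to a single halfway displacement
field ``phi_T`` that moves the template toward the learned pseudomean space;
the subject-side field is constructed as ``phi_S = -phi_T``, never predicted
separately.  The final convolution is initialized near zero so an untrained
network starts at (numerically) the identity transform — the standard
stabilizer for unsupervised registration training.

The encoder downsamples by strided 3**D convolutions; the decoder upsamples
with nearest-neighbour interpolation and concatenates the encoder feature
maps (skip connections), ending in one or more full-resolution convolutions
and the displacement head.  Channel counts default to a half-width variant
suitable for desk-scale volumes (<= 64 voxels per axis) and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .grids import DisplacementField, Volume
from .losses import full_deformations

__all__ = [
    "NetworkConfig",
    "PairInput",
    "SNet",
    "build_snet",
    "predict_halfway",
    "compose_full_deformations",
    "normalize_intensity",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the field-prediction network.

    ``field_scale`` multiplies the raw head output to give voxel-unit
    displacements; with near-zero head initialization and short training
    schedules it sets the displacement range the network can reach (default
    5, comfortably covering the few-voxel deformations of affinely
    pre-aligned brains and of the synthetic phantoms).
    """

    spatial_dims: int = 3
    enc_channels: tuple = (8, 16, 16, 16)
    dec_channels: tuple = (16, 16, 16, 16, 8)
    field_scale: float = 5.0
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.spatial_dims not in (2, 3):
            raise ValueError("spatial_dims must be 2 or 3")
        self.enc_channels = tuple(int(c) for c in self.enc_channels)
        self.dec_channels = tuple(int(c) for c in self.dec_channels)
        if not self.enc_channels or not self.dec_channels:
            raise ValueError("enc_channels and dec_channels must be non-empty")
        if any(c < 1 for c in self.enc_channels + self.dec_channels):
            raise ValueError("channel counts must be positive")
        if len(self.dec_channels) < len(self.enc_channels):
            raise ValueError(
                "decoder needs at least one conv per encoder level "
                f"({len(self.dec_channels)} < {len(self.enc_channels)})"
            )
        if self.field_scale <= 0:
            raise ValueError("field_scale must be positive")

    @property
    def downsampling_factor(self) -> int:
        return 2 ** len(self.enc_channels)


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Min–max normalization to [0, 1]; constant inputs map to zero."""
    data = np.asarray(data, dtype=float)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


@dataclass
class PairInput:
    """One template/subject pair as the network sees it.

    All three channels share one grid; the difference map is the signed
    difference of the [0, 1]-normalized intensities, template - subject.
    Channel order is fixed as (template, subject, difference).
    """

    template: Volume
    subject: Volume
    difference: Volume = None

    def __post_init__(self):
        if self.template.shape != self.subject.shape:
            raise ValueError(
                f"shape mismatch: template {self.template.shape} "
                f"vs subject {self.subject.shape}"
            )
        if self.difference is None:
            self.difference = Volume(
                self.template.data - self.subject.data, spacing=self.template.spacing
            )
        elif self.difference.shape != self.template.shape:
            raise ValueError("difference map shape mismatch")

    @classmethod
    def from_volumes(cls, template: Volume, subject: Volume) -> "PairInput":
        """Normalize both intensities to [0, 1] and build the difference map."""
        t = Volume(normalize_intensity(template.data), spacing=template.spacing)
        s = Volume(normalize_intensity(subject.data), spacing=subject.spacing)
        return cls(template=t, subject=s)

    def stacked(self) -> np.ndarray:
        """(3, *spatial) network input."""
        return np.stack(
            [self.template.data, self.subject.data, self.difference.data]
        ).astype(float)


class SNet:
    """Encoder–decoder displacement-field regressor with manual backprop."""

    def __init__(self, config: NetworkConfig, params: dict = None):
        self.config = config
        self.params = params if params is not None else self._init_params()
        self._cache = None

    # -- parameters -------------------------------------------------------
    def _init_params(self) -> dict:
        cfg = self.config
        D = cfg.spatial_dims
        rng = np.random.default_rng(cfg.seed)
        params = {}
        kshape = (3,) * D

        def he(c_out, c_in):
            std = np.sqrt(2.0 / (c_in * 3**D))
            return rng.normal(0.0, std, size=(c_out, c_in) + kshape)

        c_in = cfg.in_channels
        for i, c in enumerate(cfg.enc_channels):
            params[f"enc{i}_W"] = he(c, c_in)
            params[f"enc{i}_b"] = np.zeros(c)
            c_in = c
        n_enc = len(cfg.enc_channels)
        skip_channels = (cfg.in_channels,) + cfg.enc_channels[:-1]
        for i, c in enumerate(cfg.dec_channels):
            params[f"dec{i}_W"] = he(c, c_in)
            params[f"dec{i}_b"] = np.zeros(c)
            c_in = c
            if i < n_enc:  # after upsampling, the skip is concatenated
                c_in = c + skip_channels[n_enc - 1 - i]
        # near-zero displacement head: untrained network ~ identity transform
        params["flow_W"] = rng.normal(0.0, 1e-5, size=(D, c_in) + kshape)
        params["flow_b"] = np.zeros(D)
        return params

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray):
        cfg = self.config
        if x.ndim != cfg.spatial_dims + 1 or x.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected ({cfg.in_channels}, *spatial) input with "
                f"{cfg.spatial_dims} spatial axes, got {x.shape}"
            )
        f = cfg.downsampling_factor
        if any(s % f for s in x.shape[1:]):
            raise ValueError(
                f"spatial extents {x.shape[1:]} must be divisible by the "
                f"total downsampling factor {f}"
            )

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Predict the halfway field, shape (D, *spatial), voxel units."""
        self._check_input(x)
        cfg, p = self.config, self.params
        n_enc = len(cfg.enc_channels)
        cache = {"skips": [x], "enc": [], "dec": []}

        h = x
        for i in range(n_enc):
            z, cc = nn.conv_forward(h, p[f"enc{i}_W"], p[f"enc{i}_b"], stride=2)
            h = nn.leaky_relu(z)
            cache["enc"].append((z, cc))
            cache["skips"].append(h)

        for i in range(len(cfg.dec_channels)):
            z, cc = nn.conv_forward(h, p[f"dec{i}_W"], p[f"dec{i}_b"], stride=1)
            a = nn.leaky_relu(z)
            if i < n_enc:
                up = nn.upsample_nearest(a)
                skip = cache["skips"][n_enc - 1 - i]
                h = np.concatenate([up, skip], axis=0)
                cache["dec"].append((z, cc, a.shape[0]))
            else:
                h = a
                cache["dec"].append((z, cc, None))

        zf, ccf = nn.conv_forward(h, p["flow_W"], p["flow_b"], stride=1)
        cache["flow"] = ccf
        self._cache = cache if keep_cache else None
        return cfg.field_scale * zf

    def backward(self, g_phi: np.ndarray) -> dict:
        """Parameter gradients given d(loss)/d(predicted field).

        Requires the preceding ``forward(..., keep_cache=True)`` call.
        """
        if self._cache is None:
            raise RuntimeError("backward() requires forward(keep_cache=True) first")
        cfg, p, cache = self.config, self.params, self._cache
        n_enc = len(cfg.enc_channels)
        grads = {}

        g = cfg.field_scale * g_phi
        g, grads["flow_W"], grads["flow_b"] = nn.conv_backward(g, p["flow_W"], cache["flow"])

        skip_grads = [None] * (n_enc + 1)
        for i in reversed(range(len(cfg.dec_channels))):
            z, cc, n_up = cache["dec"][i]
            if n_up is not None:
                g_up, g_skip = g[:n_up], g[n_up:]
                j = n_enc - 1 - i
                skip_grads[j] = g_skip if skip_grads[j] is None else skip_grads[j] + g_skip
                g = nn.upsample_nearest_backward(g_up)
            g = nn.leaky_relu_backward(g, z)
            g, grads[f"dec{i}_W"], grads[f"dec{i}_b"] = nn.conv_backward(
                g, p[f"dec{i}_W"], cc
            )

        for i in reversed(range(n_enc)):
            if skip_grads[i + 1] is not None:
                g = g + skip_grads[i + 1]
            z, cc = cache["enc"][i]
            g = nn.leaky_relu_backward(g, z)
            g, grads[f"enc{i}_W"], grads[f"enc{i}_b"] = nn.conv_backward(
                g, p[f"enc{i}_W"], cc
            )
        return grads


def build_snet(cfg: NetworkConfig) -> SNet:
    """Construct a freshly initialized network from its configuration."""
    return SNet(cfg)


def predict_halfway(model: SNet, pair: PairInput) -> DisplacementField:
    """Run the network on one pair; returns the halfway field ``phi_T``.

    The subject-side field is ``negate(phi_T)`` — obtained by construction,
    never by a second prediction.
    """
    return DisplacementField(model.forward(pair.stacked()))


def compose_full_deformations(
    phi_T: DisplacementField, max_iter: int = 30, tol: float = 1e-3
):
    """Forward and backward full deformations from the halfway field.

    ``forward = compose(negate(phi_T), invert(phi_T))`` warps the subject
    image into template space; ``backward = compose(phi_T,
    invert(negate(phi_T)))`` warps the template into subject space.  The two
    are mutual approximate inverses; inversion convergence flags are carried
    on the returned fields.
    """
    return full_deformations(phi_T, max_iter=max_iter, tol=tol)
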