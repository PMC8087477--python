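"""Spatial-transformer warping of volumes by displacement fields.

``warp(I, phi)(u) = sum_{v in N(u + phi(u))} I(v) * prod_d (1 - |u_d + phi_d(u) - v_d|)``

i.e. multilinear (bilinear in 2-D, trilinear in 3-D) interpolation of the
image at the deformed coordinate, over the 2**D cell corners.  Sample
coordinates outside the grid are clamped to the boundary, so warped
intensities always stay within the input intensity range.  The operation is
differentiable with respect to ``phi`` (see :func:`warp_with_grad`), which is
what lets an image-similarity loss train a field predictor without
ground-truth deformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._interp import sample_linear, sample_linear_with_grad, sample_nearest
from .grids import DisplacementField, Volume, identity_grid

__all__ = ["WarpSettings", "warp", "warp_labels", "warp_array", "warp_with_grad"]


@dataclass
class WarpSettings:
    """Interpolation settings.

    ``interpolation``: ``"linear"`` for intensity images, ``"nearest"`` for
    label volumes (preserves label identity).  ``boundary_rule`` is always
    ``"clamp"`` (border replication); the field is listed for transparency.
    """

    interpolation: str = "linear"
    boundary_rule: str = "clamp"

    def __post_init__(self):
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.boundary_rule != "clamp":
            raise ValueError("only the 'clamp' boundary rule is supported")


def _check_pair(image: Volume, phi: DisplacementField):
    if image.shape != phi.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs field {phi.shape}")


def warp_array(data: np.ndarray, vectors: np.ndarray, interpolation: str = "linear"):
    """Array-level warp: ``out(u) = data(u + vectors(u))``."""
    points = identity_grid(data.shape) + vectors
    if interpolation == "nearest":
        return sample_nearest(data, points)
    return sample_linear(data, points)


def warp(image: Volume, phi: DisplacementField, settings: WarpSettings = None) -> Volume:
    """Warp an image by a displacement field.

    With a zero field the output equals the input bit-exactly.  Linear
    interpolation weights are non-negative and sum to 1, so the output range
    is bounded by the input range.
    """
    if settings is None:
        settings = WarpSettings()
    _check_pair(image, phi)
    if not np.all(np.isfinite(phi.vectors)):
        raise ValueError("displacement field contains non-finite values")
    out = warp_array(image.data, phi.vectors, settings.interpolation)
    return Volume(out, spacing=image.spacing)


def warp_labels(labels: Volume, phi: DisplacementField) -> Volume:
    """Nearest-neighbour resampling of an ROI label map.

    Every output value is drawn from the input label set (no interpolation
    between label ids).
    """
    if not labels.is_label_volume():
        raise ValueError("warp_labels requires a non-negative integer label volume")
    _check_pair(labels, phi)
    out = warp_array(labels.data, phi.vectors, interpolation="nearest")
    return Volume(out, spacing=labels.spacing)


def warp_with_grad(data: np.ndarray, vectors: np.ndarray):
    """Warp and the exact Jacobian of the output w.r.t. the field.

    Returns ``(warped, grad)`` where ``grad[c](u)`` is the derivative of
    ``warped(u)`` with respect to ``vectors[c](u)`` — the analytic spatial
    derivative of the interpolant at the sample point (zero where the sample
    coordinate is clamped at the boundary).  Training-path helper.
    """
    points = identity_grid(data.shape) + vectors
    return sample_linear_with_grad(np.asarray(data, dtype=float), points)
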