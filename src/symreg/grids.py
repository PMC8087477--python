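"""Grid-based containers: intensity/label volumes and dense displacement fields.

Conventions used throughout the package:

* A :class:`Volume` holds a scalar grid (2-D or 3-D) with optional per-axis
  voxel spacing in millimetres.
* A :class:`DisplacementField` stores one vector per voxel in **voxel units**,
  channel-first: ``vectors[c]`` is the displacement component along spatial
  axis ``c``.  The deformation map it represents is ``T(u) = u + phi(u)``.
* Warping is pull-back resampling: ``warp(I, phi)(u) = I(u + phi(u))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "DisplacementField", "identity_grid"]


@dataclass
class Volume:
    """A scalar intensity or integer-label grid.

    Parameters
    ----------
    data
        Array of shape ``(n1, n2)`` or ``(n1, n2, n3)``.  Intensities must be
        finite; label volumes hold non-negative integers.
    spacing
        Per-axis voxel size in mm (default isotropic 1 mm).
    """

    data: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"volume must be 2-D or 3-D, got ndim={self.data.ndim}")
        if any(n < 4 for n in self.data.shape):
            raise ValueError(
                f"all extents must be >= 4 (finite differences need an interior), "
                f"got shape {self.data.shape}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensity volume contains non-finite values")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim:
                raise ValueError("spacing length must match dimensionality")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def is_label_volume(self) -> bool:
        """True when the data look like an ROI label map."""
        if np.issubdtype(self.data.dtype, np.integer):
            return bool(np.all(self.data >= 0))
        return bool(
            np.all(self.data >= 0) and np.all(self.data == np.round(self.data))
        )


@dataclass
class DisplacementField:
    """A dense per-voxel displacement, channel-first, in voxel units.

    ``vectors`` has shape ``(D, n1, ..., nD)`` where ``D`` is the spatial
    dimensionality of the grid the field acts on.
    """

    vectors: np.ndarray
    # Metadata set by invert(); None for fields that did not pass through it.
    converged: bool = field(default=None, compare=False)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim not in (3, 4):
            raise ValueError(
                f"field must have shape (D, *spatial), got {self.vectors.shape}"
            )
        ncomp, spatial = self.vectors.shape[0], self.vectors.shape[1:]
        if ncomp != len(spatial):
            raise ValueError(
                f"component count {ncomp} != spatial dimensionality {len(spatial)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple:
        """Spatial grid shape."""
        return self.vectors.shape[1:]

    @property
    def ndim(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        shape = tuple(shape)
        return cls(np.zeros((len(shape),) + shape))

    def max_magnitude(self) -> float:
        """Largest per-voxel Euclidean displacement norm."""
        return float(np.sqrt((self.vectors**2).sum(axis=0)).max())


def identity_grid(shape) -> np.ndarray:
    """Voxel-coordinate grid ``id[c] = u_c``, shape ``(D, *shape)``."""
    return np.indices(tuple(shape), dtype=float)
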