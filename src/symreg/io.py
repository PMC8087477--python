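"""NIfTI input/output and model checkpointing.

Volumes are stored as plain NIfTI with the voxel spacing on the affine
diagonal.  Displacement fields are stored as 4-D NIfTI (last axis = vector
component) together with a JSON sidecar recording the units ("voxels") and
the composition convention, so a field file is never ambiguous about what
its numbers mean.  Checkpoints are an ``.npz`` of parameters plus a JSON
metadata sidecar (architecture, field scale, channel order, normalization).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .field_algebra import COMPOSITION_CONVENTION
from .grids import DisplacementField, Volume
from .model import NetworkConfig, SNet

__all__ = [
    "save_volume", "load_volume", "save_field", "load_field",
    "save_checkpoint", "load_checkpoint",
]

#: recorded in checkpoint metadata; see model.PairInput
CHANNEL_ORDER = ("template", "subject", "difference")
INTENSITY_NORMALIZATION = "per-volume min-max to [0, 1]"


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    return aff


def save_volume(path, volume: Volume):
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          _affine(volume.spacing))
    nib.save(img, str(path))


def load_volume(path, labels: bool = False) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if labels:
        data = np.rint(data).astype(np.int32)
    else:
        data = np.asarray(data, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return Volume(data, spacing=spacing)


def save_field(path, field: DisplacementField):
    """Field -> 4-D NIfTI (last axis = component) + JSON units sidecar."""
    path = Path(path)
    arr = np.moveaxis(field.vectors, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    sidecar = {
        "units": "voxels",
        "vector_axis": "last",
        "composition_convention": COMPOSITION_CONVENTION,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_field(path) -> DisplacementField:
    path = Path(path)
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if meta.get("units") not in (None, "voxels"):
            raise ValueError(f"unsupported field units {meta['units']!r}")
    return DisplacementField(np.moveaxis(arr, -1, 0))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def save_checkpoint(path, model: SNet):
    path = Path(path)
    np.savez(path, **model.params)
    meta = {
        "spatial_dims": model.config.spatial_dims,
        "enc_channels": list(model.config.enc_channels),
        "dec_channels": list(model.config.dec_channels),
        "field_scale": model.config.field_scale,
        "in_channels": model.config.in_channels,
        "seed": model.config.seed,
        "channel_order": list(CHANNEL_ORDER),
        "intensity_normalization": INTENSITY_NORMALIZATION,
        "displacement_units": "voxels",
    }
    meta_path = path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> SNet:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig(
        spatial_dims=meta["spatial_dims"],
        enc_channels=tuple(meta["enc_channels"]),
        dec_channels=tuple(meta["dec_channels"]),
        field_scale=meta["field_scale"],
        in_channels=meta["in_channels"],
        seed=meta.get("seed", 0),
    )
    with np.load(path) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return SNet(cfg, params=params)
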