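"""Registration quality metrics: ROI overlap (Dice) and field regularity.

Dice for ROI ``i`` is ``2|A_i ∩ B_i| / (|A_i| + |B_i|)``; the report covers
the union of nonzero ROI ids of both label maps (background, label 0, is
excluded).  An ROI present in only one volume scores 0 and is flagged
rather than silently dropped — dropping would inflate the mean.  The mean
is unweighted over ROIs (not volume-weighted).

Field regularity is audited on the composed forward field — the map
actually used to align the subject to the template — as the interior count
of voxels with a negative Jacobian determinant (folds), plus determinant
extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_algebra import FieldDiagnostics, field_diagnostics
from .grids import Volume
from .warp import warp_labels

__all__ = ["DiceReport", "dice", "evaluate_registration"]


@dataclass
class DiceReport:
    """Per-ROI and mean Dice overlap."""

    per_roi: dict
    mean: float
    #: ROI ids found in only one of the two label maps (scored 0)
    missing: list = dc_field(default_factory=list)


def dice(labels_a: Volume, labels_b: Volume) -> DiceReport:
    """Dice overlap per ROI and the unweighted mean over all nonzero ROIs."""
    if labels_a.shape != labels_b.shape:
        raise ValueError(f"shape mismatch: {labels_a.shape} vs {labels_b.shape}")
    if not (labels_a.is_label_volume() and labels_b.is_label_volume()):
        raise ValueError("dice requires non-negative integer label volumes")
    a = np.asarray(labels_a.data).astype(np.int64)
    b = np.asarray(labels_b.data).astype(np.int64)

    ids_a = set(np.unique(a)) - {0}
    ids_b = set(np.unique(b)) - {0}
    per_roi, missing = {}, []
    for roi in sorted(ids_a | ids_b):
        ma, mb = a == roi, b == roi
        if not (roi in ids_a and roi in ids_b):
            per_roi[int(roi)] = 0.0
            missing.append(int(roi))
            continue
        inter = np.count_nonzero(ma & mb)
        per_roi[int(roi)] = 2.0 * inter / (np.count_nonzero(ma) + np.count_nonzero(mb))
    mean = float(np.mean(list(per_roi.values()))) if per_roi else float("nan")
    return DiceReport(per_roi=per_roi, mean=mean, missing=missing)


def evaluate_registration(result, labels_S: Volume, labels_T: Volume
                          ) -> tuple[DiceReport, FieldDiagnostics]:
    """Score one registration: warped-label Dice and forward-field folds.

    The subject's label map is carried into template space by the forward
    field with nearest-neighbour resampling and compared against the
    template's labels; the forward field's Jacobian is audited for folds.
    """
    if labels_S.shape != result.forward.shape or labels_T.shape != result.forward.shape:
        raise ValueError("label shapes must match the registered grid")
    warped = warp_labels(labels_S, result.forward)
    report = dice(warped, labels_T)
    diagnostics = (
        result.diagnostics
        if getattr(result, "diagnostics", None) is not None
        else field_diagnostics(result.forward)
    )
    return report, diagnostics
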