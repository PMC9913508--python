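"""Evaluation algebra for resection tracking.

The preoperative tumor segmentation is partitioned against the tracked
resection cavity and (when available) the intraoperative-MRI residual
segmentation into four regions:

* **True Positive Tracking**  — tracked AND actually resected,
* **False Positive Tracking** — tracked but still residual on iMRI
  (brain shift or calibration error carved "inside" remaining tumor),
* **False Negative Tracking** — resected but never tracked
  (line-of-sight dropout, cavity collapse, en-bloc removal),
* **True Negative Tracking**  — untracked and residual.

By construction ``TP + FP + TN + FN = preoperative tumor`` exactly (in
voxel counts), and the predicted residual is::

    predicted residual = TN + FN = preop - (TP + FP)

i.e. the untracked portion of the preoperative tumor.  True Positive
Tracking is reported as a percentage of the preoperative tumor volume;
False Positive Tracking as a percentage of the residual tumor volume.

When the iMRI residual segmentation drifts outside the preoperative tumor
(intraoperative re-segmentation), the residual is clipped to the preop
mask before partitioning, since the taxonomy is defined as a partition of
the preoperative tumor; the clipped-away volume is retained for logging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volume import BinaryMask, mask_and, mask_diff, resample_mask

__all__ = [
    "TrackingConfusion",
    "tracking_confusion",
    "predicted_residual_mask",
    "predicted_residual_from_percent",
    "overestimation_pct",
    "coverage",
    "overlap",
    "case_report",
    "cohort_summary",
    "to_common_grid",
]


@dataclass
class TrackingConfusion:
    """Four-way tracking partition of the preoperative tumor and derived rates.

    Volumes are cm^3, percentages in [0, 100].  Fields that require the
    iMRI residual segmentation are ``None`` when it was not provided.
    Voxel counts on the common evaluation grid are kept alongside so exact
    partition identities can be verified without float summation error.
    """

    v_pre_cm3: float
    v_res_cm3: Optional[float]
    tp_cm3: Optional[float]
    fp_cm3: Optional[float]
    tn_cm3: Optional[float]
    fn_cm3: Optional[float]
    tracked_pct: float
    tp_pct: Optional[float]
    fp_pct: Optional[float]
    resected_imri_pct: Optional[float]
    predicted_residual_cm3: float
    clipped_residual_cm3: float = 0.0
    # exact voxel counts on the evaluation grid
    pre_voxels: int = 0
    tracked_in_pre_voxels: int = 0
    tp_voxels: Optional[int] = None
    fp_voxels: Optional[int] = None
    tn_voxels: Optional[int] = None
    fn_voxels: Optional[int] = None


def to_common_grid(*masks: Optional[BinaryMask]):
    """Resample masks onto the finest grid among them (smallest voxel volume)."""
    present = [m for m in masks if m is not None]
    if not present:
        raise ValueError("no masks given")
    finest = min(present, key=lambda m: m.geometry.voxel_volume_mm3).geometry
    return tuple(None if m is None else resample_mask(m, finest) for m in masks)


def tracking_confusion(preop: BinaryMask, tracked: BinaryMask,
                       residual: Optional[BinaryMask] = None) -> TrackingConfusion:
    """Partition the preoperative tumor against the tracked cavity.

    Masks may live on different (co-registered) grids; computation happens
    on the finest one.  ``residual`` is the iMRI residual-tumor
    segmentation; without it only coverage and the predicted residual are
    defined.  An empty preoperative tumor is an error (the percentages are
    undefined).
    """
    preop, tracked, residual = to_common_grid(preop, tracked, residual)
    n_pre = preop.count
    if n_pre == 0:
        raise ValueError("preoperative tumor mask is empty: tracking percentages are undefined")
    vv = preop.geometry.voxel_volume_mm3 / 1000.0  # cm^3 per voxel
    n_tracked_in_pre = mask_and(tracked, preop).count
    tracked_pct = 100.0 * n_tracked_in_pre / n_pre
    predicted = (n_pre - n_tracked_in_pre) * vv

    if residual is None:
        return TrackingConfusion(
            v_pre_cm3=n_pre * vv, v_res_cm3=None,
            tp_cm3=None, fp_cm3=None, tn_cm3=None, fn_cm3=None,
            tracked_pct=tracked_pct, tp_pct=None, fp_pct=None,
            resected_imri_pct=None, predicted_residual_cm3=predicted,
            pre_voxels=n_pre, tracked_in_pre_voxels=n_tracked_in_pre,
        )

    raw_res = residual.count
    residual = mask_and(residual, preop)
    n_res = residual.count
    clipped = (raw_res - n_res) * vv
    resected = mask_diff(preop, residual)
    tp = mask_and(tracked, resected).count
    fp = mask_and(tracked, residual).count
    fn = mask_diff(resected, tracked).count
    tn = mask_diff(residual, tracked).count
    return TrackingConfusion(
        v_pre_cm3=n_pre * vv,
        v_res_cm3=n_res * vv,
        tp_cm3=tp * vv, fp_cm3=fp * vv, tn_cm3=tn * vv, fn_cm3=fn * vv,
        tracked_pct=tracked_pct,
        tp_pct=100.0 * tp / n_pre,
        fp_pct=(100.0 * fp / n_res) if n_res else 0.0,
        resected_imri_pct=100.0 * (n_pre - n_res) / n_pre,
        predicted_residual_cm3=predicted,
        clipped_residual_cm3=clipped,
        pre_voxels=n_pre, tracked_in_pre_voxels=n_tracked_in_pre,
        tp_voxels=tp, fp_voxels=fp, tn_voxels=tn, fn_voxels=fn,
    )


def predicted_residual_mask(preop: BinaryMask, tracked: BinaryMask) -> BinaryMask:
    """Untracked portion of the preoperative tumor (preop minus tracked).

    Its volume equals ``predicted_residual_cm3`` of the confusion exactly.
    """
    preop, tracked = to_common_grid(preop, tracked)
    return mask_diff(preop, tracked)


def predicted_residual_from_percent(v_pre_cm3: float, tracked_pct: float) -> float:
    """Predicted residual volume from a preop volume and a tracked percentage:
    ``v_pre * (1 - tracked_pct / 100)``."""
    if not (0.0 <= tracked_pct <= 100.0):
        raise ValueError("tracked_pct must be in [0, 100]")
    return v_pre_cm3 * (1.0 - tracked_pct / 100.0)


def overestimation_pct(predicted_cm3: float, actual_cm3: float, v_pre_cm3: float) -> float:
    """Residual over/under-estimation as a percentage of the preoperative volume."""
    if v_pre_cm3 <= 0:
        raise ValueError("preoperative volume must be > 0")
    return 100.0 * (predicted_cm3 - actual_cm3) / v_pre_cm3


def coverage(lesion: BinaryMask, tracked: BinaryMask) -> float:
    """Fraction of the lesion covered by the tracked cavity: |T ∩ L| / |L|."""
    lesion, tracked = to_common_grid(lesion, tracked)
    n = lesion.count
    if n == 0:
        raise ValueError("lesion mask is empty: coverage undefined")
    return mask_and(tracked, lesion).count / n


def overlap(cavity: BinaryMask, tracked: BinaryMask, method: str = "dice") -> float:
    """Overlap between the true cavity and the tracked cavity.

    ``method='dice'`` (default): 2|A ∩ B| / (|A| + |B|).
    ``method='directional'``: |A ∩ B| / |A|, the fraction of the true
    cavity covered by tracking.
    """
    cavity, tracked = to_common_grid(cavity, tracked)
    na, nb = cavity.count, tracked.count
    inter = mask_and(cavity, tracked).count
    if method == "dice":
        if na + nb == 0:
            raise ValueError("both masks empty: overlap undefined")
        return 2.0 * inter / (na + nb)
    if method == "directional":
        if na == 0:
            raise ValueError("cavity mask empty: directional overlap undefined")
        return inter / na
    raise ValueError(f"unknown overlap method {method!r}")


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "Preoperative Tumor Volume (cm3)",
    "Residual Tumor Volume (cm3)",
    "Tumor Resected Based on iMRI (%)",
    "Tumor Resected Based on Tool-Tip Tracking (%)",
    "True Positive Tracking (%)",
    "False Positive Tracking (%)",
    "Predicted Residual Tumor Volume (cm3)",
]


def case_report(conf: TrackingConfusion, case_id, rounded: bool = True) -> dict:
    """One per-case report row with conventional clinical column names.

    "Tumor Resected Based on Tool-Tip Tracking (%)" is the tracked coverage
    of the preoperative tumor (including any false-positive sliver inside
    the residual); the stricter TP-only percentage is reported separately
    as "True Positive Tracking (%)".  With ``rounded`` (the print
    convention: volumes and percentages to 1 decimal) the row is
    report-ready; otherwise full precision is preserved (e.g. for JSON).
    """
    vals = [
        conf.v_pre_cm3,
        conf.v_res_cm3,
        conf.resected_imri_pct,
        conf.tracked_pct,
        conf.tp_pct,
        conf.fp_pct,
        conf.predicted_residual_cm3,
    ]
    if rounded:
        vals = [None if v is None else round(float(v), 1) for v in vals]
    row = {"Case": case_id}
    row.update(dict(zip(_REPORT_COLUMNS, vals)))
    return row


def cohort_summary(rows: Sequence[dict]) -> pd.DataFrame:
    """Aggregate per-case rows into mean/median/min/max summary rows."""
    if not rows:
        raise ValueError("no case rows to aggregate")
    df = pd.DataFrame(rows)
    num = df.drop(columns=["Case"], errors="ignore").apply(pd.to_numeric, errors="coerce")
    out = pd.DataFrame(
        [num.mean(), num.median(), num.min(), num.max()],
        index=["Mean", "Median", "Minimum", "Maximum"],
    )
    out.index.name = "Statistic"
    return out
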