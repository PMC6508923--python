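"""Segmentation accuracy metrics and volume quantification.

Overlap metrics follow the standard voxel-count confusion definitions,
DC = 2TP / (FP + 2TP + FN), R = TP/(TP+FN), P = TP/(TP+FP); the Hausdorff
distance is the symmetric max-min Euclidean distance between the two masks'
boundary voxel sets, computed in physical millimetres using voxel spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volio import LabelMap

__all__ = [
    "ConfusionCounts",
    "AccuracyReport",
    "confusion",
    "dice_precision_recall",
    "hausdorff",
    "volume_ml",
    "boundary_voxels",
    "evaluate_labels",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyReport:
    dice: float
    precision: float
    recall: float
    hausdorff_mm: float


def _as_bool(m: LabelMap | np.ndarray) -> np.ndarray:
    return m.labels > 0 if isinstance(m, LabelMap) else np.asarray(m) > 0


def confusion(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts over the full grid."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def dice_precision_recall(c: ConfusionCounts) -> tuple[float, float, float]:
    """(DC, P, R) from confusion counts.

    Degenerate cases: with no positives anywhere (tp+fp+fn == 0) all three
    are defined as 1; a zero denominator with positives present gives 0.
    """
    if c.tp + c.fp + c.fn == 0:
        return 1.0, 1.0, 1.0
    dc = 2 * c.tp / (c.fp + 2 * c.tp + c.fn)
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return dc, p, r


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (k, 3) of surface voxels: positive with a 6-neighbor negative
    (grid edges count as outside)."""
    m = np.asarray(mask) > 0
    padded = np.pad(m, 1, constant_values=False)
    interior = np.ones_like(m)
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    return np.argwhere(m & ~interior)


def hausdorff(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """Symmetric Hausdorff distance between boundary sets, in mm.

    Spacing is taken from ``pred`` when it is a LabelMap and not given
    explicitly.  Both masks empty -> 0 with a warning; exactly one empty is
    an error naming the empty side.
    """
    if spacing is None:
        if isinstance(pred, LabelMap):
            spacing = pred.spacing
        elif isinstance(truth, LabelMap):
            spacing = truth.spacing
        else:
            spacing = (1.0, 1.0, 1.0)
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    p_any, t_any = bool(p.any()), bool(t.any())
    if not p_any and not t_any:
        warnings.warn("both masks empty; Hausdorff distance defined as 0", stacklevel=2)
        return 0.0
    if not p_any:
        raise ValueError("prediction mask is empty; Hausdorff distance undefined")
    if not t_any:
        raise ValueError("truth mask is empty; Hausdorff distance undefined")
    sp = np.asarray(spacing, dtype=np.float64)
    bp = boundary_voxels(p) * sp
    bt = boundary_voxels(t) * sp
    d_pt = cKDTree(bt).query(bp)[0].max()
    d_tp = cKDTree(bp).query(bt)[0].max()
    return float(max(d_pt, d_tp))


def volume_ml(mask: LabelMap | np.ndarray, spacing=None) -> tuple[float, float]:
    """(mm^3, mL) of a binary mask: voxel count x dx*dy*dz."""
    if spacing is None:
        if not isinstance(mask, LabelMap):
            raise ValueError("spacing required when mask is a bare array")
        spacing = mask.spacing
    n = int(np.count_nonzero(_as_bool(mask)))
    mm3 = n * float(np.prod(np.asarray(spacing, dtype=np.float64)))
    return mm3, mm3 / 1000.0


def evaluate_labels(
    pred: LabelMap, truth: LabelMap, labels: list[int] | None = None
) -> dict[int, AccuracyReport]:
    """Per-label accuracy rows (one binary comparison per label id)."""
    if labels is None:
        labels = [l for l in truth.label_set if l != 0]
    out = {}
    for lab in labels:
        c = confusion(pred.labels == lab, truth.labels == lab)
        dc, p, r = dice_precision_recall(c)
        hd = hausdorff(pred.labels == lab, truth.labels == lab, spacing=truth.spacing)
        out[lab] = AccuracyReport(dice=dc, precision=p, recall=r, hausdorff_mm=hd)
    return out
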