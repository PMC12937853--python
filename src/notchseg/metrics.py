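"""Evaluation metrics: overlap (DSC, IoU) and boundary distances (HD95,
ASSD) in physical millimetres.

Overlap metrics are computed from exact confusion counts:

    DSC = 2 TP / (2 TP + FN + FP)        IoU = TP / (TP + FN + FP)

which satisfy IoU = DSC / (2 - DSC).  Boundary metrics operate on the
sets of foreground pixels that touch background through a 4-neighbour
(the image border counts as background); pixel centres are scaled by the
pixel spacing, and distances are Euclidean point-to-set distances.

HD95 takes the 95th percentile (linear interpolation between order
statistics) of the *pooled* bidirectional nearest-distance multiset by
default; the alternative reading -- the max of the two directed 95th
percentiles -- is available via `directed=True`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class BoundaryPointSet:
    """Boundary pixel centres in millimetres."""

    points: np.ndarray  # (n, 2) float, (row_mm, col_mm)
    spacing_mm: float

    def __len__(self):
        return len(self.points)


@dataclass
class MetricReport:
    dsc: float
    iou: float
    hd95_mm: float | None
    assd_mm: float | None
    per_class: dict = field(default_factory=dict)


def confusion_counts(pred_mask, target_mask, positive_label: int = 1
                     ) -> ConfusionCounts:
    p = np.asarray(pred_mask)
    t = np.asarray(target_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pp = p == positive_label
    tt = t == positive_label
    tp = int(np.sum(pp & tt))
    fp = int(np.sum(pp & ~tt))
    fn = int(np.sum(~pp & tt))
    tn = int(np.sum(~pp & ~tt))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0  # nothing to find, nothing found: perfect absence
    return 2.0 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return c.tp / denom


def extract_boundary(mask, spacing_mm: float) -> BoundaryPointSet:
    """Foreground pixels with at least one background 4-neighbour; the
    image border counts as background."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask has no boundary")
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = binary_erosion(m, structure=cross, border_value=0)
    rows, cols = np.nonzero(m & ~interior)
    pts = np.stack([rows, cols], axis=1).astype(np.float64) * spacing_mm
    return BoundaryPointSet(pts, spacing_mm)


def _directed_min_distances(a: BoundaryPointSet, b: BoundaryPointSet
                            ) -> np.ndarray:
    """For each point of `a`, the distance to the nearest point of `b`."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("boundary distance is undefined for an empty set")
    d, _ = cKDTree(b.points).query(a.points, k=1)
    return np.atleast_1d(d)


def hd95(b1: BoundaryPointSet, b2: BoundaryPointSet,
         directed: bool = False) -> float:
    """95th-percentile Hausdorff distance in mm (pooled convention by
    default; `directed=True` takes the max of two directed percentiles)."""
    d12 = _directed_min_distances(b1, b2)
    d21 = _directed_min_distances(b2, b1)
    if directed:
        return float(
            max(np.percentile(d12, 95), np.percentile(d21, 95))
        )
    return float(np.percentile(np.concatenate([d12, d21]), 95))


def assd(b1: BoundaryPointSet, b2: BoundaryPointSet) -> float:
    """Average symmetric surface distance in mm."""
    d12 = _directed_min_distances(b1, b2)
    d21 = _directed_min_distances(b2, b1)
    return float((d12.sum() + d21.sum()) / (len(b1) + len(b2)))


def evaluate_pair(pred_mask, target_mask, spacing_mm: float,
                  positive_label: int = 1) -> MetricReport:
    """Full report for one binary class of one prediction/target pair.

    Boundary metrics are reported as None (missing, never 0) when either
    boundary set is empty.
    """
    c = confusion_counts(pred_mask, target_mask, positive_label)
    p_bin = np.asarray(pred_mask) == positive_label
    t_bin = np.asarray(target_mask) == positive_label
    h = a = None
    if p_bin.any() and t_bin.any():
        bp = extract_boundary(p_bin, spacing_mm)
        bt = extract_boundary(t_bin, spacing_mm)
        h = hd95(bp, bt)
        a = assd(bp, bt)
    return MetricReport(dsc=dsc(c), iou=iou(c), hd95_mm=h, assd_mm=a)


def evaluate_multiclass(pred_mask, target_mask, spacing_mm: float,
                        n_classes: int) -> MetricReport:
    """One binary report per non-background class plus their mean."""
    per = {
        k: evaluate_pair(pred_mask, target_mask, spacing_mm, positive_label=k)
        for k in range(1, n_classes)
    }

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    rep = MetricReport(
        dsc=_mean([r.dsc for r in per.values()]),
        iou=_mean([r.iou for r in per.values()]),
        hd95_mm=_mean([r.hd95_mm for r in per.values()]),
        assd_mm=_mean([r.assd_mm for r in per.values()]),
        per_class=per,
    )
    return rep
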