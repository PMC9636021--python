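"""Segmentation evaluation: matched IoU, Jaccard-vs-threshold curves,
errors per cell, edge-mask filtering, and cell-diameter metrics.

The Jaccard index at threshold τ counts a one-to-one matched (ground
truth, prediction) pair as a true positive when its IoU ≥ τ and reports
TP/(TP+FP+FN); swept over τ ∈ [0.5, 1.0] it summarizes accuracy from
"roughly found" to "pixel-perfect".  Errors per cell instead counts
surplus predictions: a predicted cell is assigned to a ground-truth cell
when ≥ 75% of its area lies inside it, surplus assignments beyond the
first are errors, and an unmatched ground-truth cell scores one error.

Two diameter notions: the equivalent-area diameter 2√(A/π), and the
effective diameter 6·φ̄ (six times the mean of the distance field over
the region).  For a disk of radius R the mean interior distance is R/3,
so the two agree; for filaments growing in length at constant width the
effective diameter stays fixed while the area diameter diverges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .core_labels import LabelImage, as_label_array
from .eikonal import DistanceField

__all__ = [
    "MatchResult",
    "MetricsReport",
    "DiameterEstimate",
    "match_instances",
    "jaccard_at_threshold",
    "ji_curve",
    "errors_per_cell",
    "filter_edge_masks",
    "equivalent_area_diameter",
    "effective_diameter",
    "evaluate",
]

DEFAULT_TAUS = np.round(np.arange(0.50, 1.0001, 0.05), 2)


@dataclass
class MatchResult:
    """One-to-one GT↔prediction matching by maximum total IoU."""

    gt_ids: np.ndarray
    pred_ids: np.ndarray
    iou_matrix: np.ndarray            # |GT| × |pred|, dense, values in [0,1]
    pairs: list[tuple[int, int]]      # (gt index, pred index) matched pairs
    matched_ious: np.ndarray          # IoU per matched pair

    @property
    def n_gt(self) -> int:
        return len(self.gt_ids)

    @property
    def n_pred(self) -> int:
        return len(self.pred_ids)


@dataclass
class MetricsReport:
    taus: np.ndarray
    ji: np.ndarray
    mean_matched_iou: float
    errors_per_cell: np.ndarray
    n_gt: int
    n_pred: int

    def to_dict(self) -> dict:
        return {
            "taus": [float(t) for t in self.taus],
            "ji": [float(j) for j in self.ji],
            "mean_matched_iou": float(self.mean_matched_iou),
            "errors_per_cell": [int(e) for e in self.errors_per_cell],
            "total_errors": int(self.errors_per_cell.sum()),
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
        }


@dataclass
class DiameterEstimate:
    equivalent_area_d: Optional[float] = None
    effective_d: Optional[float] = None


def _overlap_counts(gt: np.ndarray, pred: np.ndarray):
    """Pixel-count contingency between two labelings (background excluded)."""
    both = (gt > 0) | (pred > 0)
    g, p = gt[both].astype(np.int64), pred[both].astype(np.int64)
    gt_ids = np.unique(gt[gt > 0])
    pred_ids = np.unique(pred[pred > 0])
    g_idx = np.searchsorted(gt_ids, g)
    p_idx = np.searchsorted(pred_ids, p)
    # joint histogram over (gt, pred) including the background row/col
    key = np.where(g > 0, g_idx + 1, 0) * (len(pred_ids) + 1) + np.where(p > 0, p_idx + 1, 0)
    counts = np.bincount(key, minlength=(len(gt_ids) + 1) * (len(pred_ids) + 1))
    table = counts.reshape(len(gt_ids) + 1, len(pred_ids) + 1)
    gt_areas = np.array([np.count_nonzero(gt == i) for i in gt_ids], dtype=np.int64)
    pred_areas = np.array([np.count_nonzero(pred == i) for i in pred_ids], dtype=np.int64)
    return gt_ids, pred_ids, table[1:, 1:], gt_areas, pred_areas


def match_instances(gt, pred) -> MatchResult:
    """Match instances one-to-one by maximizing total IoU (Hungarian
    assignment over the sparse overlap matrix); deterministic and
    order-independent.  Pairs with zero IoU are discarded."""
    g, p = as_label_array(gt), as_label_array(pred)
    if g.shape != p.shape:
        raise ValueError("ground-truth and prediction shapes differ")
    gt_ids, pred_ids, inter, ga, pa = _overlap_counts(g, p)
    union = ga[:, None] + pa[None, :] - inter
    iou = np.zeros(inter.shape, dtype=np.float64)
    np.divide(inter, union, out=iou, where=union > 0)
    pairs: list[tuple[int, int]] = []
    ious: list[float] = []
    if iou.size:
        ri, ci = linear_sum_assignment(-iou)
        for r, c in zip(ri, ci):
            if iou[r, c] > 0:
                pairs.append((int(r), int(c)))
                ious.append(float(iou[r, c]))
    return MatchResult(gt_ids, pred_ids, iou, pairs, np.asarray(ious))


def jaccard_at_threshold(match: MatchResult, tau: float) -> float:
    """JI(τ) = TP/(TP+FP+FN); TP = matched pairs with IoU ≥ τ.

    An empty prediction against an empty ground truth is perfect
    agreement (JI = 1)."""
    if match.n_gt == 0 and match.n_pred == 0:
        return 1.0
    tp = int((match.matched_ious >= tau).sum())
    fp = match.n_pred - tp
    fn = match.n_gt - tp
    denom = tp + fp + fn
    return tp / denom if denom else 1.0


def ji_curve(match: MatchResult, taus: Sequence[float] = DEFAULT_TAUS) -> np.ndarray:
    return np.array([jaccard_at_threshold(match, t) for t in taus])


def errors_per_cell(gt, pred) -> np.ndarray:
    """Segmentation errors per ground-truth cell.

    A predicted cell is assigned to a GT cell iff |pred ∩ gt| / |pred|
    ≥ 0.75 (three quarters of the prediction lies inside the cell).  The
    error count per GT cell is the number of surplus assignments
    (matches − 1), or 1 when nothing is assigned to it.  Invariant under
    relabeling of either input.
    """
    g, p = as_label_array(gt), as_label_array(pred)
    if g.shape != p.shape:
        raise ValueError("ground-truth and prediction shapes differ")
    gt_ids, pred_ids, inter, _ga, pa = _overlap_counts(g, p)
    if len(gt_ids) == 0:
        return np.zeros(0, dtype=np.int64)
    if len(pred_ids) == 0:
        return np.ones(len(gt_ids), dtype=np.int64)
    ratio = inter / pa[None, :]
    assigned = ratio >= 0.75
    matches = assigned.sum(axis=1)
    return np.where(matches == 0, 1, matches - 1).astype(np.int64)


def filter_edge_masks(labels, min_area: int = 9) -> LabelImage:
    """Remove small masks touching the image border (area < min_area).

    The default threshold is the minimal well-defined cell footprint of
    9 px (a 3-px-wide cell); interior masks and large border-crossing
    masks are retained.
    """
    arr = as_label_array(labels).copy()
    border = np.zeros(arr.shape, dtype=bool)
    for ax in range(arr.ndim):
        sl0 = tuple(0 if a == ax else slice(None) for a in range(arr.ndim))
        sl1 = tuple(-1 if a == ax else slice(None) for a in range(arr.ndim))
        border[sl0] = True
        border[sl1] = True
    edge_ids = np.unique(arr[border & (arr > 0)])
    for i in edge_ids:
        mask = arr == i
        if mask.sum() < min_area:
            arr[mask] = 0
    return LabelImage(arr)


def equivalent_area_diameter(region) -> DiameterEstimate:
    """Diameter of the circle of equivalent area, d = 2√(A/π)."""
    mask = np.asarray(region).astype(bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    return DiameterEstimate(equivalent_area_d=2.0 * np.sqrt(area / np.pi))


def effective_diameter(phi, region=None) -> DiameterEstimate:
    """Effective diameter d = 6·φ̄ from the mean distance field.

    For a disk of radius R, φ̄ = R/3, so d = 2R matches the equivalent-
    area diameter; for constant-width filaments it is length-invariant.
    ``region`` defaults to the whole foreground (per-image scope).
    """
    arr = phi.phi if isinstance(phi, DistanceField) else np.asarray(phi, dtype=np.float64)
    mask = arr > 0 if region is None else np.asarray(region).astype(bool)
    if not mask.any():
        raise ValueError("empty region")
    return DiameterEstimate(effective_d=6.0 * float(arr[mask].mean()))


def evaluate(gt, pred, taus: Sequence[float] = DEFAULT_TAUS) -> MetricsReport:
    """Per-image report: JI curve, mean matched IoU, errors per cell."""
    match = match_instances(gt, pred)
    curve = ji_curve(match, taus)
    mean_iou = float(match.matched_ious.mean()) if match.matched_ious.size else 0.0
    return MetricsReport(
        taus=np.asarray(taus, dtype=np.float64),
        ji=curve,
        mean_matched_iou=mean_iou,
        errors_per_cell=errors_per_cell(gt, pred),
        n_gt=match.n_gt,
        n_pred=match.n_pred,
    )
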