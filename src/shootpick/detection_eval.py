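"""Shoot-identification evaluation: IoU, threshold-swept matching, mAP/mAR
and the F-beta summary.

mAP and mAR here are *point* precision and recall averaged over a grid of
IoU matching thresholds (default 0.50:0.05:0.95, the COCO-style 10-threshold
sweep), not areas under a score-swept PR curve.  The F-beta combination uses
a (1 + beta) numerator,

    F_beta = (1 + beta) * mAP * mAR / (beta^2 * mAP + mAR),

which differs from the textbook (1 + beta^2) form; the textbook form is
available via ``standard=True``.  beta defaults to 2, weighting recall of
the sweep (mAR) down relative to precision — for a picker that images the
same bush from several angles, a shoot missed in one view is recoverable,
a spurious detection is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import InstanceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCounts",
    "EvalSummary",
    "DEFAULT_IOU_GRID",
    "iou_box",
    "iou_mask",
    "match_at_threshold",
    "mean_ap_ar",
    "paper_f_beta",
    "evaluate",
]

#: 10 IoU matching thresholds, 0.50 to 0.95 step 0.05.
DEFAULT_IOU_GRID: tuple[float, ...] = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN tallies at one IoU matching threshold."""

    tp: int
    fp: int
    fn: int
    iou_threshold: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


@dataclass(frozen=True)
class EvalSummary:
    """mAP/mAR over an IoU grid plus their F-beta combination."""

    map: float
    mar: float
    f_beta: float
    beta: float
    grid: tuple[float, ...]
    per_threshold: tuple[MatchCounts, ...] = field(default=())


def iou_box(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax1 >= ax2 or ay1 >= ay2 or bx1 >= bx2 or by1 >= by2:
        raise ValueError("degenerate (zero-area) box")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def iou_mask(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two equal-shape binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.warning("IoU of two empty masks defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _pairwise_iou(
    preds: Sequence[InstanceRecord], truths: Sequence[InstanceRecord], mode: str
) -> np.ndarray:
    fn = iou_mask if mode == "mask" else iou_box
    out = np.zeros((len(preds), len(truths)))
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            out[i, j] = fn(p.mask if mode == "mask" else p.box,
                           t.mask if mode == "mask" else t.box)
    return out


def match_at_threshold(
    preds: Sequence[InstanceRecord],
    truths: Sequence[InstanceRecord],
    thr: float,
    mode: str = "mask",
    iou_matrix: Optional[np.ndarray] = None,
) -> MatchCounts:
    """Greedy one-to-one matching of predictions to ground truth at one
    IoU threshold.

    Predictions are visited in descending score order (score ties broken by
    ascending index; missing scores count as 1.0).  Each prediction claims
    its best-IoU still-unmatched truth and is a TP iff that IoU >= ``thr``;
    each truth matches at most once.
    """
    if not 0.0 < thr <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {thr}")
    if mode not in ("box", "mask"):
        raise ValueError(f"mode must be 'box' or 'mask', got {mode!r}")
    if iou_matrix is None:
        iou_matrix = _pairwise_iou(preds, truths, mode)
    order = sorted(range(len(preds)),
                   key=lambda i: (-(preds[i].score if preds[i].score is not None else 1.0), i))
    matched = np.zeros(len(truths), dtype=bool)
    tp = 0
    for i in order:
        if matched.all() or len(truths) == 0:
            break
        ious = np.where(matched, -1.0, iou_matrix[i])
        j = int(np.argmax(ious))
        if ious[j] >= thr:
            matched[j] = True
            tp += 1
    return MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp,
                       iou_threshold=thr)


def mean_ap_ar(
    preds: Sequence[InstanceRecord],
    truths: Sequence[InstanceRecord],
    grid: Sequence[float] = DEFAULT_IOU_GRID,
    mode: str = "mask",
) -> tuple[float, float]:
    """Mean point-precision (mAP) and point-recall (mAR) over the IoU grid.

    At each threshold, precision = TP/(TP+FP) and recall = TP/(TP+FN); the
    means divide by the grid length.  Empty denominators count as 0.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("IoU grid must be non-empty and strictly increasing")
    if not preds and not truths:
        logger.warning("no predictions and no truths: mAP = mAR = 0")
        return 0.0, 0.0
    iou_matrix = _pairwise_iou(preds, truths, mode)
    counts = [match_at_threshold(preds, truths, t, mode, iou_matrix=iou_matrix)
              for t in grid]
    return (float(np.mean([c.precision for c in counts])),
            float(np.mean([c.recall for c in counts])))


def paper_f_beta(map: float, mar: float, beta: float = 2.0,
                 standard: bool = False) -> float:
    """F-beta combination of mAP and mAR.

    Default numerator is (1 + beta); ``standard=True`` uses the textbook
    (1 + beta^2).  Returns 0 (with a warning) when both inputs are 0.
    """
    if not (0.0 <= map <= 1.0 and 0.0 <= mar <= 1.0):
        raise ValueError("mAP and mAR must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if map == 0.0 and mar == 0.0:
        logger.warning("mAP = mAR = 0: F-beta defined as 0")
        return 0.0
    num = (1.0 + beta**2 if standard else 1.0 + beta) * map * mar
    return num / (beta**2 * map + mar)


def evaluate(
    preds: Sequence[InstanceRecord],
    truths: Sequence[InstanceRecord],
    grid: Sequence[float] = DEFAULT_IOU_GRID,
    mode: str = "mask",
    beta: float = 2.0,
    standard_f: bool = False,
) -> EvalSummary:
    """Full detection evaluation: per-threshold counts, mAP, mAR, F-beta."""
    grid = list(grid)
    map_, mar = mean_ap_ar(preds, truths, grid=grid, mode=mode)
    iou_matrix = _pairwise_iou(preds, truths, mode) if (preds or truths) else None
    per = tuple(match_at_threshold(preds, truths, t, mode, iou_matrix=iou_matrix)
                for t in grid) if (preds or truths) else ()
    return EvalSummary(map=map_, mar=mar,
                       f_beta=paper_f_beta(map_, mar, beta, standard=standard_f),
                       beta=beta, grid=tuple(grid), per_threshold=per)
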