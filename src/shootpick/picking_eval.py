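"""Picking-point localization evaluation.

Predicted and true picking points are matched one-to-one within a pixel
tolerance; the tallies follow the detection confusion matrix for points:

* ED — a true picking point exists and was detected (matched pair),
* EN — a true point exists but was not detected (unmatched truth),
* ND — no true point exists where one was detected (unmatched prediction),

giving precision = ED/(ED+ND) and recall = ED/(ED+EN).  Matching is greedy
by ascending pairwise distance, which is optimal whenever distances are
unambiguous (every prediction clearly nearest its own truth).

When evaluating a set of images, matching runs per image and the counts are
pooled before computing precision/recall (micro-averaging), matching the
aggregate-count style of reporting ("N points detected, M correct").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["PickMatchCounts", "match_points", "precision_recall", "pooled_counts"]

Point = Tuple[float, float]


@dataclass(frozen=True)
class PickMatchCounts:
    """ED/EN/ND tallies from matching predicted to true picking points."""

    ed: int
    en: int
    nd: int
    tolerance: float

    def __add__(self, other: "PickMatchCounts") -> "PickMatchCounts":
        if other.tolerance != self.tolerance:
            raise ValueError("cannot pool counts computed at different tolerances")
        return PickMatchCounts(self.ed + other.ed, self.en + other.en,
                               self.nd + other.nd, self.tolerance)


def match_points(
    pred: Sequence[Point], truth: Sequence[Point], tolerance: float = 10.0
) -> PickMatchCounts:
    """Match predicted to true picking points within ``tolerance`` pixels.

    Pairs are accepted greedily by ascending Euclidean distance, one-to-one;
    a pair counts only if its distance <= tolerance.  Distance ties break by
    (prediction index, truth index).  The default tolerance of 10 px is
    roughly 1% of the 1512x1008 px image diagonal typical for close-up
    shoot photography.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(pred) == 0 or len(truth) == 0:
        return PickMatchCounts(ed=0, en=len(truth), nd=len(pred), tolerance=tolerance)
    dist = cdist(pred, truth)
    pairs = [(dist[i, j], i, j) for i in range(len(pred)) for j in range(len(truth))
             if dist[i, j] <= tolerance]
    pairs.sort()
    used_p = np.zeros(len(pred), dtype=bool)
    used_t = np.zeros(len(truth), dtype=bool)
    ed = 0
    for _, i, j in pairs:
        if not used_p[i] and not used_t[j]:
            used_p[i] = used_t[j] = True
            ed += 1
    return PickMatchCounts(ed=ed, en=len(truth) - ed, nd=len(pred) - ed,
                           tolerance=tolerance)


def pooled_counts(per_image: Iterable[PickMatchCounts]) -> PickMatchCounts:
    """Pool per-image tallies into one aggregate (micro-averaging)."""
    it = iter(per_image)
    try:
        total = next(it)
    except StopIteration:
        raise ValueError("no counts to pool") from None
    for c in it:
        total = total + c
    return total


def precision_recall(counts: PickMatchCounts) -> tuple[float, float]:
    """precision = ED/(ED+ND), recall = ED/(ED+EN); empty denominators give 0."""
    if counts.ed + counts.nd == 0:
        logger.warning("no predicted points: precision defined as 0")
        precision = 0.0
    else:
        precision = counts.ed / (counts.ed + counts.nd)
    if counts.ed + counts.en == 0:
        logger.warning("no true points: recall defined as 0")
        recall = 0.0
    else:
        recall = counts.ed / (counts.ed + counts.en)
    return precision, recall
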