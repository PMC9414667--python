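"""Reference implementations of the two-stage detector training math.

These are the printed formulas of the Mask R-CNN style loss — anchor
labeling by IoU, greedy non-maximum suppression, smooth-L1 box regression,
classification and per-pixel mask cross-entropy, and the composite RPN /
head losses — implemented on plain arrays so they can be exercised and
checked without any network.  No forward pass, anchor geometry or box
offset parameterization is involved: every operation consumes
already-computed probabilities, offsets and mask grids.

The total loss decomposes as L = L_RPN + L_head with

    L_RPN  = (1/N_cls1) sum_i L_cls(p_i, p_i*) + lambda1 (1/N_reg1) sum_i p_i* L_reg(t_i, t_i*)
    L_head = (1/N_cls2) sum_i L_cls + lambda2 (1/N_reg2) sum_i p_i* L_reg
             + gamma (1/N_mask) sum_i L_mask(s_i, s_i*)

where p* gates the regression term to positive samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSample",
    "BoxSample",
    "MaskSample",
    "LossWeights",
    "EPS",
    "assign_anchor_label",
    "nms_filter",
    "smooth_l1",
    "box_reg_loss",
    "cls_loss",
    "mask_loss",
    "rpn_loss",
    "head_loss",
    "total_loss",
]

#: Probability clamp for logarithms.
EPS = 1e-12

#: Anchors overlapping ground truth above this IoU are positive samples.
POSITIVE_IOU = 0.7
#: Anchors below this IoU are negative samples; in between they are ignored.
NEGATIVE_IOU = 0.3


@dataclass(frozen=True)
class AnchorSample:
    """One RPN anchor: predicted foreground probability and its label."""

    p: float
    p_star: int
    label: Literal["positive", "negative", "ignore"] = "positive"

    def __post_init__(self):
        if self.label == "positive" and self.p_star != 1:
            raise ValueError("positive anchors require p_star = 1")
        if self.label == "negative" and self.p_star != 0:
            raise ValueError("negative anchors require p_star = 0")


@dataclass(frozen=True)
class BoxSample:
    """Predicted and ground-truth 4-vector box regression offsets."""

    t: tuple[float, float, float, float]
    t_star: tuple[float, float, float, float]


@dataclass(frozen=True)
class MaskSample:
    """Predicted probability grid and binary ground-truth grid, same shape."""

    s: np.ndarray
    s_star: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        s_star = np.asarray(self.s_star, dtype=float)
        if s.shape != s_star.shape:
            raise ValueError(f"mask shape mismatch: {s.shape} vs {s_star.shape}")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "s_star", s_star)


@dataclass(frozen=True)
class LossWeights:
    """Balancing weights and normalizers of the composite loss.

    The balancing parameters lambda1, lambda2, gamma are all adjustable and
    default to 1.  Normalizers are batch-size counts (>= 1).
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    gamma: float = 1.0
    n_cls1: int = 1
    n_reg1: int = 1
    n_cls2: int = 1
    n_reg2: int = 1
    n_mask: int = 1

    def __post_init__(self):
        for name in ("n_cls1", "n_reg1", "n_cls2", "n_reg2", "n_mask"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def assign_anchor_label(iou: float) -> str:
    """Label an anchor by its best IoU with ground truth.

    IoU > 0.7 -> ``"positive"``; IoU < 0.3 -> ``"negative"``; anchors in
    between are ``"ignore"`` and take no part in training.
    """
    if not 0.0 <= iou <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou}")
    if iou > POSITIVE_IOU:
        return "positive"
    if iou < NEGATIVE_IOU:
        return "negative"
    return "ignore"


def nms_filter(
    boxes: Sequence[tuple[Sequence[float], float]], threshold: float = 0.7
) -> list[int]:
    """Greedy non-maximum suppression over scored boxes.

    ``boxes`` is a sequence of ((x1, y1, x2, y2), score) pairs.  Boxes are
    visited in descending score order (ties by ascending index); any
    remaining box with IoU > ``threshold`` to a kept box is suppressed.
    Returns the indices of kept boxes, in keep order.
    """
    from .detection_eval import iou_box

    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i][1], i))
    kept: list[int] = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(i)
        for j in order:
            if j not in suppressed and j != i and j not in kept:
                if iou_box(boxes[i][0], boxes[j][0]) > threshold:
                    suppressed.add(j)
    return kept


def smooth_l1(x: float) -> float:
    """Smooth-L1: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise.

    Quadratic near zero (stable gradients), linear in the tails (robust to
    outlier offsets); continuous with continuous first derivative at |x|=1.
    """
    ax = abs(x)
    return 0.5 * x * x if ax < 1.0 else ax - 0.5


def box_reg_loss(sample: BoxSample) -> float:
    """Box regression loss: smooth-L1 summed over the 4 offset components."""
    return float(sum(smooth_l1(t_s - t) for t, t_s in zip(sample.t, sample.t_star)))


def _clamped_log(p: np.ndarray) -> np.ndarray:
    if np.any(p < EPS):
        logger.warning("probability clamped at %.0e before log", EPS)
    return np.log(np.clip(p, EPS, None))


def cls_loss(p: float, p_star: int, variant: str = "bce") -> float:
    """Classification loss for one sample.

    ``variant="bce"`` (default) is the full binary cross-entropy
    -[p* log p + (1 - p*) log(1 - p)].  ``variant="printed"`` is the
    truncated form -p* log p, which assigns zero loss to negative samples.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p_star not in (0, 1):
        raise ValueError(f"p_star must be 0 or 1, got {p_star}")
    if variant == "printed":
        return float(-_clamped_log(np.asarray(p))) if p_star == 1 else 0.0
    if variant != "bce":
        raise ValueError(f"unknown cls_loss variant {variant!r}")
    target = p if p_star == 1 else 1.0 - p
    return float(-_clamped_log(np.asarray(target)))


def mask_loss(sample: MaskSample) -> float:
    """Per-pixel binary cross-entropy of one predicted mask, averaged over
    pixels.  Single-category: only the mask of the sample's own class enters,
    so there is no competition between classes."""
    s, s_star = sample.s, sample.s_star
    ce = -(s_star * _clamped_log(s) + (1.0 - s_star) * _clamped_log(1.0 - s))
    return float(ce.mean())


def _active(anchors: Sequence[AnchorSample]) -> list[AnchorSample]:
    return [a for a in anchors if a.label != "ignore"]


def rpn_loss(
    anchors: Sequence[AnchorSample],
    boxes: Sequence[BoxSample],
    w: LossWeights = LossWeights(),
    cls_variant: str = "bce",
) -> float:
    """Region-proposal loss: normalized classification term plus the
    lambda1-weighted regression term.  ``boxes`` are the regression samples
    of the positive anchors, in the same order; ignore-labeled anchors are
    excluded from the classification sum and the p* gate zeroes the
    regression contribution of negatives."""
    active = _active(anchors)
    cls_term = sum(cls_loss(a.p, a.p_star, variant=cls_variant) for a in active)
    positives = [a for a in active if a.p_star == 1]
    if len(boxes) != len(positives):
        raise ValueError(
            f"expected one box sample per positive anchor "
            f"({len(positives)}), got {len(boxes)}")
    reg_term = sum(box_reg_loss(b) for b in boxes)
    return cls_term / w.n_cls1 + w.lambda1 * reg_term / w.n_reg1


def head_loss(
    cls: Sequence[AnchorSample],
    boxes: Sequence[BoxSample],
    masks: Sequence[MaskSample],
    w: LossWeights = LossWeights(),
    cls_variant: str = "bce",
) -> float:
    """Head-network loss: classification + lambda2-weighted regression +
    gamma-weighted mask cross-entropy."""
    active = _active(cls)
    cls_term = sum(cls_loss(a.p, a.p_star, variant=cls_variant) for a in active)
    positives = [a for a in active if a.p_star == 1]
    if len(boxes) != len(positives):
        raise ValueError(
            f"expected one box sample per positive sample "
            f"({len(positives)}), got {len(boxes)}")
    reg_term = sum(box_reg_loss(b) for b in boxes)
    mask_term = sum(mask_loss(m) for m in masks)
    return (cls_term / w.n_cls2 + w.lambda2 * reg_term / w.n_reg2
            + w.gamma * mask_term / w.n_mask)


def total_loss(
    rpn_anchors: Sequence[AnchorSample],
    rpn_boxes: Sequence[BoxSample],
    head_cls: Sequence[AnchorSample],
    head_boxes: Sequence[BoxSample],
    head_masks: Sequence[MaskSample],
    w: LossWeights = LossWeights(),
    cls_variant: str = "bce",
) -> float:
    """Composite training loss L = L_RPN + L_head."""
    return (rpn_loss(rpn_anchors, rpn_boxes, w, cls_variant)
            + head_loss(head_cls, head_boxes, head_masks, w, cls_variant))
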