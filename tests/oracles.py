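"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — scalar loops, BFS flood fill,
orientation sweeps — and shares no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def point_in_polygon(px: float, py: float, poly) -> bool:
    """Crossing-number point-in-polygon test; points on an edge count inside."""
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and \
               min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                return True  # on the edge
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def rasterize_bruteforce(poly, height: int, width: int) -> np.ndarray:
    out = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            out[r, c] = point_in_polygon(c + 0.5, r + 0.5, poly)
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """BFS flood fill; returns the list of pixel sets."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2] \
                                and not seen[r2, c2]:
                            seen[r2, c2] = True
                            q.append((r2, c2))
                comps.append(comp)
    return comps


def min_rect_area_sweep(points: np.ndarray, step_deg: float = 0.01) -> float:
    """Minimum bounding-rectangle area over orientations swept at step_deg.

    The sweep only needs the extreme points, so the input is reduced to its
    convex hull first (scipy) before the brute-force orientation scan.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    if len(pts) > 3:
        pts = pts[ConvexHull(pts).vertices]
    angles = np.radians(np.arange(0.0, 90.0, step_deg))
    cos, sin = np.cos(angles), np.sin(angles)
    xs = cos[:, None] * pts[None, :, 0] + sin[:, None] * pts[None, :, 1]
    ys = -sin[:, None] * pts[None, :, 0] + cos[:, None] * pts[None, :, 1]
    areas = (xs.max(1) - xs.min(1)) * (ys.max(1) - ys.min(1))
    return float(areas.min())


def greedy_match_counts(pred_ious, scores, thr: float) -> tuple[int, int, int]:
    """Pure-python greedy matcher: pred_ious is a list of per-prediction IoU
    lists against every truth; returns (tp, fp, fn)."""
    n_pred = len(pred_ious)
    n_truth = len(pred_ious[0]) if n_pred else 0
    order = sorted(range(n_pred), key=lambda i: (-scores[i], i))
    taken = [False] * n_truth
    tp = 0
    for i in order:
        best_j, best_iou = -1, -1.0
        for j in range(n_truth):
            if not taken[j] and pred_ious[i][j] > best_iou:
                best_j, best_iou = j, pred_ious[i][j]
        if best_j >= 0 and best_iou >= thr:
            taken[best_j] = True
            tp += 1
    return tp, n_pred - tp, n_truth - tp


def smooth_l1_scalar(x: float) -> float:
    return 0.5 * x * x if abs(x) < 1 else abs(x) - 0.5


def bce_scalar(p: float, target: int, eps: float = 1e-12) -> float:
    p = min(max(p, eps), 1.0)
    q = min(max(1.0 - p, eps), 1.0)
    return -(target * math.log(p) + (1 - target) * math.log(q))


def rpn_loss_scalar(anchors, boxes, lam1, n_cls, n_reg) -> float:
    """anchors: (p, p_star, label) triples; boxes: (t, t_star) for positives."""
    cls = sum(bce_scalar(p, ps) for p, ps, lab in anchors if lab != "ignore")
    reg = sum(sum(smooth_l1_scalar(ts - t) for t, ts in zip(tv, tsv))
              for tv, tsv in boxes)
    return cls / n_cls + lam1 * reg / n_reg


def mask_loss_scalar(s, s_star) -> float:
    total = 0.0
    n = 0
    for row_s, row_t in zip(s, s_star):
        for p, t in zip(row_s, row_t):
            total += bce_scalar(p, int(t))
            n += 1
    return total / n
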