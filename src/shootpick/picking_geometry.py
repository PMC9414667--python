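"""Picking-point localization from a single instance mask.

The pipeline mirrors how a harvesting robot turns a segmented tea shoot into
a cut instruction: keep the largest connected domain of the mask (the shoot
main body), circumscribe it with the minimum-area oriented rectangle, read
the shoot axis off the rectangle's long side, and place the picking point a
small fraction (default 2%) of the shoot length up from the bottom end of
the axis.  The axis inclination doubles as the suggested knife angle.

Angles are in degrees in [0, 180), measured from the +x (rightward) image
axis toward -y (upward on screen), i.e. visually counterclockwise.  A
vertical shoot has theta = 90.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely import MultiPoint
from skimage import measure

from .io_formats import InstanceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "ConnectedComponent",
    "MinAreaRect",
    "ShootAxis",
    "PickingPoint",
    "EmptyMaskError",
    "connected_components",
    "main_mask",
    "min_area_rect",
    "shoot_axis",
    "picking_point",
    "locate",
]

#: A binary mask is any 2-D array interpretable as booleans.
BinaryMask = np.ndarray

_SQUARE_TOL = 1e-9


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one on-pixel."""


@dataclass(frozen=True)
class ConnectedComponent:
    """A maximal set of mutually connected on-pixels.

    ``pixels`` is an (N, 2) integer array of (row, col) coordinates in
    lexicographic order; ``area`` equals N.
    """

    pixels: np.ndarray

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def min_pixel(self) -> tuple[int, int]:
        """Lexicographically smallest (row, col) pixel — the tie-break key."""
        return tuple(self.pixels[0])

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.pixels[:, 0], self.pixels[:, 1]] = True
        return out


@dataclass(frozen=True)
class MinAreaRect:
    """Minimum-area oriented rectangle circumscribing a pixel set.

    ``center`` is (x, y); ``long_axis_angle`` is the inclination of the long
    side in degrees in [0, 180).
    """

    center: tuple[float, float]
    long_side: float
    short_side: float
    long_axis_angle: float

    def corners(self) -> np.ndarray:
        """The 4 rectangle corners as (x, y) rows."""
        th = math.radians(self.long_axis_angle)
        u = np.array([math.cos(th), -math.sin(th)])   # along long side
        v = np.array([math.sin(th), math.cos(th)])    # along short side
        c = np.asarray(self.center)
        h, w = self.long_side / 2.0, self.short_side / 2.0
        return np.array([c + h * u + w * v, c + h * u - w * v,
                         c - h * u - w * v, c - h * u + w * v])


@dataclass(frozen=True)
class ShootAxis:
    """The shoot's central axis: the long mid-line of its bounding rectangle."""

    bottom: tuple[float, float]
    top: tuple[float, float]
    theta: float

    @property
    def length(self) -> float:
        return math.dist(self.bottom, self.top)


@dataclass(frozen=True)
class PickingPoint:
    """A picking point (x, y in px from the image upper-left corner) with the
    suggested knife angle ``theta`` (degrees) and the along-axis ``fraction``
    it was placed at."""

    x: float
    y: float
    theta: float
    fraction: float


def connected_components(mask: BinaryMask, connectivity: int = 8) -> list[ConnectedComponent]:
    """Split a binary mask into connected domains, largest first.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default: it keeps thin diagonal stems in one piece).  Components are
    disjoint, cover all on-pixels, and are sorted by area descending with
    ties broken by the smallest (row, col) pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    comps = []
    for lab in range(1, labeled.max() + 1):
        pixels = np.argwhere(labeled == lab)  # argwhere is already lexicographic
        comps.append(ConnectedComponent(pixels=pixels))
    comps.sort(key=lambda c: (-c.area, c.min_pixel))
    return comps


def main_mask(components: Sequence[ConnectedComponent]) -> ConnectedComponent:
    """Select the shoot main body: the maximum-area connected domain.

    Picking points are more likely to lie in larger connected domains, so the
    largest one is taken as the shoot's main mask.  Area ties go to the
    component with the lexicographically smallest (row, col) pixel.
    """
    if not components:
        raise EmptyMaskError("instance mask has no connected components")
    return min(components, key=lambda c: (-c.area, c.min_pixel))


def _rect_from_corners(corners: np.ndarray) -> MinAreaRect:
    """Build a MinAreaRect from 4 rectangle corners ((x, y) rows, in order)."""
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        long_side, short_side, axis = float(l1), float(l2), e1
    else:
        long_side, short_side, axis = float(l2), float(l1), e2
    center = tuple(corners[:4].mean(axis=0))
    if abs(long_side - short_side) <= _SQUARE_TOL * max(long_side, 1.0):
        # Exact square: orientation of the long axis is ambiguous.  Tea
        # shoots generally grow vertically, so report vertical.
        angle = 90.0
    else:
        angle = math.degrees(math.atan2(-axis[1], axis[0])) % 180.0
        if abs(angle - 180.0) < 1e-12:
            angle = 0.0
    return MinAreaRect(center=center, long_side=long_side,
                       short_side=short_side, long_axis_angle=angle)


def min_area_rect(component: ConnectedComponent) -> MinAreaRect:
    """Minimum circumscribed rectangle of a connected domain.

    The rectangle is fitted to the convex hull of the pixel unit-square
    corners (not the centers), so every pixel square is fully covered and
    tiny components stay stable.  The optimum has one side collinear with a
    hull edge (rotating-calipers property).  A single pixel yields a 1x1
    square reported as vertical.
    """
    if component.area == 0:
        raise EmptyMaskError("cannot circumscribe an empty component")
    rc = component.pixels
    # unit-square corners in (x, y)
    corners = np.concatenate([
        rc[:, ::-1] + offset for offset in
        (np.array([0, 0]), np.array([1, 0]), np.array([0, 1]), np.array([1, 1]))
    ]).astype(float)
    rect_geom = MultiPoint(corners).minimum_rotated_rectangle
    pts = np.asarray(rect_geom.exterior.coords)[:4]
    return _rect_from_corners(pts)


def shoot_axis(rect: MinAreaRect) -> ShootAxis:
    """Derive the shoot axis from the rectangle: the segment through the
    center, parallel to the long side, spanning the full long side.

    The endpoint further down the image (larger y) is the ``bottom``; if
    both endpoints share y (horizontal axis), the one with larger x is
    bottom.  ``theta`` equals the rectangle's long-axis angle.
    """
    if abs(rect.long_side - rect.short_side) <= _SQUARE_TOL * max(rect.long_side, 1.0):
        logger.warning("square bounding rectangle: axis orientation ambiguous, "
                       "using the vertical convention")
    th = math.radians(rect.long_axis_angle)
    u = np.array([math.cos(th), -math.sin(th)])  # points screen-up for theta in (0,180)
    c = np.asarray(rect.center, dtype=float)
    e1 = c + (rect.long_side / 2.0) * u
    e2 = c - (rect.long_side / 2.0) * u
    bottom, top = ((e1, e2) if (e1[1], e1[0]) > (e2[1], e2[0]) else (e2, e1))
    return ShootAxis(bottom=tuple(bottom), top=tuple(top), theta=rect.long_axis_angle)


def picking_point(axis: ShootAxis, fraction: float = 0.02) -> PickingPoint:
    """Place the picking point ``fraction`` of the shoot length up from the
    axis bottom (default 2%, where picking points sit just below the stem /
    leaf intersection on a vertically growing shoot)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    bx, by = axis.bottom
    tx, ty = axis.top
    return PickingPoint(x=bx + fraction * (tx - bx), y=by + fraction * (ty - by),
                        theta=axis.theta, fraction=fraction)


def locate(
    instances: Iterable[InstanceRecord],
    fraction: float = 0.02,
    connectivity: int = 8,
) -> list[PickingPoint]:
    """Run the full chain on each instance: connected domains -> main mask ->
    minimum circumscribed rectangle -> shoot axis -> picking point.

    Returns one :class:`PickingPoint` per non-empty instance, in input order;
    instances with empty masks are skipped with a warning.
    """
    points = []
    for i, rec in enumerate(instances):
        comps = connected_components(rec.mask, connectivity=connectivity)
        if not comps:
            logger.warning("instance %d has an empty mask; skipped", i)
            continue
        rect = min_area_rect(main_mask(comps))
        points.append(picking_point(shoot_axis(rect), fraction=fraction))
    return points
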