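"""Reading and writing annotation, mask and result files.

Supported inputs are LabelMe-style polygon JSON documents and integer-labeled
mask rasters (PNG).  Both are converted to :class:`InstanceRecord` objects,
the internal per-instance model consumed by the geometry and evaluation
modules.  Picking-point results are written as CSV with a JSON mirror.

Coordinate convention: x = column (rightward), y = row (downward), origin at
the image upper-left corner, 0-based.  A pixel (r, c) is the unit square
[c, c+1) x [r, r+1); a polygon covers a pixel iff it covers the pixel center
(c + 0.5, r + 0.5), boundary included.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "PolygonAnnotation",
    "InstanceRecord",
    "AnnotationError",
    "read_labelme",
    "read_label_image",
    "rasterize_polygon",
    "mask_to_box",
    "masks_to_label_image",
    "write_pick_results",
    "read_pick_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ("instance", "x", "y", "theta_deg")


class AnnotationError(ValueError):
    """Raised when an annotation document is malformed or fails validation."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """A polygon annotation document: image size plus labeled polygon shapes."""

    image_height: int
    image_width: int
    shapes: list[tuple[str, list[tuple[float, float]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, points in self.shapes:
            if len(points) < 3:
                raise AnnotationError(
                    f"shape {label!r} has {len(points)} points; polygons need >= 3"
                )


@dataclass
class InstanceRecord:
    """One segmented instance: a binary mask, its tight box, optional score.

    ``mask`` is an H x W boolean array on the full image grid.  ``box`` is
    (x1, y1, x2, y2) in pixel units under the unit-square pixel model, so a
    single on-pixel at (r, c) has box (c, r, c+1, r+1).  ``score`` is absent
    (None) for ground truth.
    """

    mask: np.ndarray
    box: tuple[float, float, float, float]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise AnnotationError("instance mask must be 2-D")
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise AnnotationError(f"degenerate box {self.box}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise AnnotationError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def mask_to_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    """Tight axis-aligned bounds of a mask's on-pixel unit squares."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise AnnotationError("cannot compute bounds of an empty mask")
    return (float(cols.min()), float(rows.min()),
            float(cols.max()) + 1.0, float(rows.max()) + 1.0)


def rasterize_polygon(
    points: Sequence[tuple[float, float]], height: int, width: int
) -> np.ndarray:
    """Rasterize a polygon under the pixel-center coverage rule.

    A pixel is on iff its center (c + 0.5, r + 0.5) lies in the closed
    polygon (interior or boundary).
    """
    poly = Polygon(points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    x1, y1, x2, y2 = poly.bounds
    c0 = max(int(np.floor(x1 - 0.5)), 0)
    r0 = max(int(np.floor(y1 - 0.5)), 0)
    c1 = min(int(np.ceil(x2 + 0.5)), width)
    r1 = min(int(np.ceil(y2 + 0.5)), height)
    mask = np.zeros((height, width), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.intersects_xy(poly, cc + 0.5, rr + 0.5)
    mask[r0:r1, c0:c1] = inside
    return mask


def _require(doc: dict, key: str):
    if key not in doc:
        raise AnnotationError(f"annotation document missing field {key!r}")
    return doc[key]


def _parse_document(document: Union[str, bytes, dict]):
    if isinstance(document, (str, bytes)):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"invalid JSON: {exc}") from exc
    else:
        doc = document
    height = int(_require(doc, "imageHeight"))
    width = int(_require(doc, "imageWidth"))
    if height <= 0 or width <= 0:
        raise AnnotationError("imageHeight/imageWidth must be positive")
    shapes = []
    for i, shape in enumerate(_require(doc, "shapes")):
        if "points" not in shape:
            raise AnnotationError(f"shapes[{i}] missing field 'points'")
        pts = [(float(x), float(y)) for x, y in shape["points"]]
        if len(pts) < 3:
            raise AnnotationError(f"shapes[{i}] has {len(pts)} points; need >= 3")
        shapes.append((str(shape.get("label", "")), pts, shape.get("score")))
    return height, width, shapes


def parse_labelme(document: Union[str, bytes, dict]) -> PolygonAnnotation:
    """Parse a LabelMe-dialect JSON document (text or already-decoded dict)."""
    height, width, shapes = _parse_document(document)
    return PolygonAnnotation(height, width, [(lab, pts) for lab, pts, _ in shapes])


def read_labelme(
    document: Union[str, bytes, dict, Path],
    label: Optional[str] = "shoot",
) -> list[InstanceRecord]:
    """Read a LabelMe-dialect annotation into per-instance records.

    Parameters
    ----------
    document
        JSON text, a decoded dict, or a path to a ``.json`` file.
    label
        Shape label to keep; shapes with other labels are skipped with a
        warning.  ``None`` accepts every shape.

    Returns one :class:`InstanceRecord` per kept polygon, in document order.
    Shapes carrying an optional ``score`` key keep it on the record.
    """
    if isinstance(document, Path):
        document = document.read_text()
    height, width, shapes = _parse_document(document)
    records: list[InstanceRecord] = []
    for lab, points, score in shapes:
        if label is not None and lab != label:
            logger.warning("ignoring shape with label %r (expected %r)", lab, label)
            continue
        mask = rasterize_polygon(points, height, width)
        if not mask.any():
            logger.warning("polygon %r rasterized to an empty mask; skipped", lab)
            continue
        records.append(InstanceRecord(mask=mask, box=mask_to_box(mask),
                                      score=None if score is None else float(score)))
    return records


def read_label_image(image: Union[np.ndarray, Path, str]) -> list[InstanceRecord]:
    """Read an integer-labeled raster: background 0, one record per positive label.

    Records are returned in ascending label order.  An all-zero raster yields
    an empty list.
    """
    if isinstance(image, (str, Path)):
        image = np.asarray(Image.open(image))
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise AnnotationError("label image must be a single-channel 2-D raster")
    labels = np.unique(arr)
    records = []
    for lab in labels[labels > 0]:
        mask = arr == lab
        records.append(InstanceRecord(mask=mask, box=mask_to_box(mask)))
    return records


def masks_to_label_image(records: Sequence[InstanceRecord]) -> np.ndarray:
    """Re-encode instance masks into a labeled raster (labels 1..n, uint16).

    Overlapping pixels take the label of the later instance.
    """
    if not records:
        return np.zeros((1, 1), dtype=np.uint16)
    out = np.zeros(records[0].mask.shape, dtype=np.uint16)
    for i, rec in enumerate(records, start=1):
        out[rec.mask] = i
    return out


def write_pick_results(results, destination: Union[str, Path]) -> tuple[Path, Path]:
    """Write picking-point results as CSV plus a JSON mirror.

    ``results`` is an iterable of ``(instance_id, PickingPoint)`` pairs.  The
    CSV has header ``instance,x,y,theta_deg``; coordinates and angles are
    rounded to 2 decimals in files (full precision stays in memory).  Returns
    the (csv_path, json_path) written.
    """
    destination = Path(destination)
    json_path = destination.with_suffix(".json")
    rows = [(int(i), float(p.x), float(p.y), float(p.theta)) for i, p in results]
    try:
        with open(destination, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(RESULT_COLUMNS)
            for i, x, y, theta in rows:
                writer.writerow([i, f"{x:.2f}", f"{y:.2f}", f"{theta:.2f}"])
        mirror = {str(i): {"x": round(x, 2), "y": round(y, 2),
                           "theta_deg": round(theta, 2)} for i, x, y, theta in rows}
        json_path.write_text(json.dumps(mirror, indent=1))
    except OSError as exc:
        raise IOError(f"cannot write results to {destination}: {exc}") from exc
    return destination, json_path


def read_pick_results(path: Union[str, Path]) -> list[tuple[int, float, float, float]]:
    """Read a results CSV back as (instance, x, y, theta_deg) tuples."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append((int(row["instance"]), float(row["x"]),
                        float(row["y"]), float(row["theta_deg"])))
    return out
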