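"""Synthetic shoot-mask generator with analytically known ground truth.

No public dataset of annotated tea-shoot images exists, so the geometry and
evaluation modules are exercised on simulated masks instead.  A shoot is
modeled as a capsule — a straight spine segment swept with a circular
cross-section — optionally widening toward the tip (the bud) and carrying
interior holes.  Because the capsule's axis, tip-to-tip length and picking
point are known in closed form, localization error can be measured exactly.

Defaults emulate close-up field photographs at 1512 x 1008 px: shoots
120-260 px long and 12-26 px wide, growing near-vertically (axis angles
drawn from 60-120 degrees).  Scenes can force a fraction of shoot pairs to
overlap, mimicking the dense canopies that make instance separation hard.

Angle convention matches :mod:`shootpick.picking_geometry`: degrees in
[0, 180) from the +x image axis toward screen-up; vertical = 90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely import unary_union
from shapely.geometry import box as shapely_box

from .io_formats import InstanceRecord, mask_to_box
from .picking_geometry import PickingPoint, ShootAxis

__all__ = [
    "ShootSpec",
    "SceneTruth",
    "SceneGenerationError",
    "generate_shoot",
    "generate_scene",
    "perturb",
    "mask_to_polygon",
    "scene_to_labelme",
    "write_scene",
]

DEFAULT_IMAGE_SIZE = (1008, 1512)  # (H, W): the study's capture resolution


class SceneGenerationError(RuntimeError):
    """Raised when a scene cannot be packed within the attempt budget."""


@dataclass(frozen=True)
class ShootSpec:
    """Parameters of one synthetic shoot.

    ``length`` is the tip-to-tip extent along the axis, ``width`` the stem
    diameter; ``bud_bulge`` widens the cross-section toward the tip by up to
    that factor; ``hole_rate`` is the fraction of the area punched out as
    interior holes (never disconnecting the main body below 50% of area).
    """

    length: float
    width: float
    axis_angle: float
    center: tuple[float, float]
    bud_bulge: float = 0.0
    hole_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.length > self.width > 0:
            raise ValueError("require length > width > 0")
        if not 0.0 <= self.axis_angle < 180.0:
            raise ValueError("axis_angle must lie in [0, 180)")
        if self.bud_bulge < 0:
            raise ValueError("bud_bulge must be >= 0")
        if not 0.0 <= self.hole_rate < 0.5:
            raise ValueError("hole_rate must lie in [0, 0.5)")


@dataclass
class SceneTruth:
    """Ground truth for one synthetic image: per-instance record, axis angle
    and true picking point."""

    instances: list[tuple[InstanceRecord, float, PickingPoint]]
    image_size: tuple[int, int]


def _axis_dir(angle_deg: float) -> np.ndarray:
    th = math.radians(angle_deg)
    return np.array([math.cos(th), -math.sin(th)])  # screen-up for angle in (0,180)


def generate_shoot(
    spec: ShootSpec,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    fraction: float = 0.02,
) -> tuple[np.ndarray, ShootAxis, PickingPoint]:
    """Rasterize one capsule-shaped shoot and return it with its truth.

    The returned axis runs tip-to-tip along the spine; the truth picking
    point sits at ``fraction`` of the length up from the bottom tip (the
    same placement rule the localizer applies, so recovery is exact by
    construction up to rasterization).  Deterministic for a fixed spec.
    """
    H, W = image_size
    u = _axis_dir(spec.axis_angle)
    c = np.asarray(spec.center, dtype=float)
    r0 = spec.width / 2.0
    r_top = r0 * (1.0 + spec.bud_bulge)
    half = spec.length / 2.0
    bottom_tip = c - half * u
    top_tip = c + half * u
    a = bottom_tip + r0 * u       # bottom cap center
    b = top_tip - r_top * u       # top cap center

    lateral = max(r0, r_top)
    for p in (bottom_tip, top_tip):
        if not (lateral <= p[0] <= W - lateral and lateral <= p[1] <= H - lateral):
            raise ValueError(
                f"shoot (center {spec.center}, length {spec.length}) exceeds "
                f"the {W}x{H} image bounds")

    # rasterize: pixel center inside iff distance to spine <= local radius
    pad = int(np.ceil(lateral)) + 2
    x1 = max(int(min(a[0], b[0]) - pad), 0)
    x2 = min(int(max(a[0], b[0]) + pad) + 1, W)
    y1 = max(int(min(a[1], b[1]) - pad), 0)
    y2 = min(int(max(a[1], b[1]) + pad) + 1, H)
    cc, rr = np.meshgrid(np.arange(x1, x2) + 0.5, np.arange(y1, y2) + 0.5)
    ab = b - a
    seg_len2 = float(ab @ ab)
    px = cc - a[0]
    py = rr - a[1]
    t = np.clip((px * ab[0] + py * ab[1]) / seg_len2, 0.0, 1.0)
    dx = px - t * ab[0]
    dy = py - t * ab[1]
    radius = r0 * (1.0 + spec.bud_bulge * t**3)
    inside = dx * dx + dy * dy <= radius * radius
    mask = np.zeros((H, W), dtype=bool)
    mask[y1:y2, x1:x2] = inside

    if spec.hole_rate > 0:
        _punch_holes(mask, spec, a, ab, r0, seed=spec.seed)

    axis = ShootAxis(bottom=tuple(bottom_tip), top=tuple(top_tip),
                     theta=spec.axis_angle)
    pick = PickingPoint(
        x=bottom_tip[0] + fraction * (top_tip[0] - bottom_tip[0]),
        y=bottom_tip[1] + fraction * (top_tip[1] - bottom_tip[1]),
        theta=spec.axis_angle, fraction=fraction)
    return mask, axis, pick


def _punch_holes(mask: np.ndarray, spec: ShootSpec, a: np.ndarray,
                 ab: np.ndarray, r0: float, seed: int) -> None:
    """Punch circular interior holes in place, spending at most
    ``hole_rate`` of the mask area.  Holes keep a >= 1.5 px margin to the
    capsule boundary, so the body stays connected."""
    rng = np.random.default_rng(seed)
    H, W = mask.shape
    budget = spec.hole_rate * mask.sum()
    spent = 0.0
    for _ in range(40):
        if spent >= budget:
            break
        radius = rng.uniform(1.0, max(1.2, r0 / 2.0 - 1.5))
        t = rng.uniform(0.15, 0.85)
        local_r = r0 * (1.0 + spec.bud_bulge * t**3)
        max_off = local_r - radius - 1.5
        if max_off <= 0:
            continue
        off = rng.uniform(-max_off, max_off)
        n = np.array([-ab[1], ab[0]]) / np.hypot(*ab)
        hc = a + t * ab + off * n
        x1 = max(int(hc[0] - radius) - 1, 0)
        x2 = min(int(hc[0] + radius) + 2, W)
        y1 = max(int(hc[1] - radius) - 1, 0)
        y2 = min(int(hc[1] + radius) + 2, H)
        cc, rr = np.meshgrid(np.arange(x1, x2) + 0.5, np.arange(y1, y2) + 0.5)
        hole = (cc - hc[0]) ** 2 + (rr - hc[1]) ** 2 <= radius**2
        spent += np.count_nonzero(mask[y1:y2, x1:x2] & hole)
        mask[y1:y2, x1:x2] &= ~hole


def generate_scene(
    n: int,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    angle_range: tuple[float, float] = (60.0, 120.0),
    overlap_fraction: float = 0.0,
    seed: int = 0,
    length_range: tuple[float, float] = (120.0, 260.0),
    width_range: tuple[float, float] = (12.0, 26.0),
    bud_bulge_range: tuple[float, float] = (0.0, 0.3),
    hole_rate: float = 0.0,
    fraction: float = 0.02,
    max_attempts: int = 200,
) -> SceneTruth:
    """Generate a scene of ``n`` shoots with serialized ground truth.

    ``overlap_fraction`` requests that fraction of shoots be placed in
    overlapping pairs (mask IoU > 0), emulating dense canopies.  Placement
    is by bounded rejection sampling; an infeasible packing raises
    :class:`SceneGenerationError` reporting the achieved count.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = image_size
    pairs_needed = math.ceil(overlap_fraction * n / 2.0)
    instances: list[tuple[InstanceRecord, float, PickingPoint]] = []
    masks: list[np.ndarray] = []

    for i in range(n):
        overlap_with: Optional[int] = i - 1 if (i < 2 * pairs_needed and i % 2 == 1) else None
        placed = False
        for _ in range(max_attempts):
            length = rng.uniform(*length_range)
            width = rng.uniform(*width_range)
            angle = rng.uniform(*angle_range)
            margin = length / 2.0 + width
            if 2 * margin >= min(H, W):
                continue
            if overlap_with is not None:
                prev_c = np.asarray(instances[overlap_with][0].box).reshape(2, 2).mean(axis=0)
                shift = rng.uniform(width / 4.0, width) * _axis_dir(rng.uniform(0, 360))
                cx, cy = prev_c + shift
                cx = float(np.clip(cx, margin, W - margin))
                cy = float(np.clip(cy, margin, H - margin))
            else:
                cx = rng.uniform(margin, W - margin)
                cy = rng.uniform(margin, H - margin)
            spec = ShootSpec(length=length, width=width, axis_angle=angle,
                             center=(cx, cy), bud_bulge=rng.uniform(*bud_bulge_range),
                             hole_rate=hole_rate,
                             seed=int(rng.integers(0, 2**31 - 1)))
            try:
                mask, axis, pick = generate_shoot(spec, image_size, fraction=fraction)
            except ValueError:
                continue
            if not mask.any() or not (0 <= pick.x < W and 0 <= pick.y < H):
                continue
            if overlap_with is not None and not (mask & masks[overlap_with]).any():
                continue
            instances.append((InstanceRecord(mask=mask, box=mask_to_box(mask)),
                              axis.theta, pick))
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place shoot {i + 1} of {n}; achieved {len(instances)}")
    return SceneTruth(instances=instances, image_size=(H, W))


def perturb(
    mask: np.ndarray,
    boundary_noise: float = 0.0,
    fragment_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Degrade a mask the way an imperfect segmenter would.

    ``boundary_noise`` flips each boundary pixel (on-pixels touching the
    background and vice versa) with that probability, jittering the outline.
    ``fragment_rate`` adds detached small blobs totalling at most that
    fraction of the mask area, at >= 3 px clearance from the mask, emulating
    spurious mask fragments.  The largest component keeps the plurality of
    area for rates well below 0.5.  Deterministic for a fixed seed.
    """
    if not (0.0 <= boundary_noise < 1.0 and 0.0 <= fragment_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    rng = np.random.default_rng(seed)
    if boundary_noise > 0 and mask.any():
        eroded = ndimage.binary_erosion(mask)
        dilated = ndimage.binary_dilation(mask)
        inner = mask & ~eroded
        outer = dilated & ~mask
        out[inner] = rng.random(np.count_nonzero(inner)) >= boundary_noise
        out[outer] = rng.random(np.count_nonzero(outer)) < boundary_noise
    if fragment_rate > 0 and mask.any():
        H, W = mask.shape
        budget = fragment_rate * mask.sum()
        forbidden = ndimage.binary_dilation(mask, iterations=7)
        spent = 0
        for _ in range(200):
            if spent >= budget:
                break
            radius = rng.uniform(1.5, 3.5)
            cx = rng.uniform(radius, W - radius)
            cy = rng.uniform(radius, H - radius)
            x1, x2 = int(cx - radius) - 1, int(cx + radius) + 2
            y1, y2 = int(cy - radius) - 1, int(cy + radius) + 2
            x1, y1 = max(x1, 0), max(y1, 0)
            x2, y2 = min(x2, W), min(y2, H)
            cc, rr = np.meshgrid(np.arange(x1, x2) + 0.5, np.arange(y1, y2) + 0.5)
            blob = (cc - cx) ** 2 + (rr - cy) ** 2 <= radius**2
            if (blob & forbidden[y1:y2, x1:x2]).any():
                continue
            spent += np.count_nonzero(blob & ~out[y1:y2, x1:x2])
            out[y1:y2, x1:x2] |= blob
    return out


def mask_to_polygon(mask: np.ndarray) -> list[tuple[float, float]]:
    """Exact pixel-boundary polygon (exterior ring) of a mask.

    Built as the union of the on-pixel unit squares; re-rasterizing the
    returned polygon under the pixel-center rule reproduces the mask exactly
    for connected hole-free masks (holes are filled by the exterior ring).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    boxes = []
    for r in range(mask.shape[0]):
        row = mask[r]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.uint8), [0]))))
        for c1, c2 in edges.reshape(-1, 2):
            boxes.append(shapely_box(float(c1), float(r), float(c2), float(r + 1)))
    geom = unary_union(boxes)
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    return [(float(x), float(y)) for x, y in geom.exterior.coords[:-1]]


def scene_to_labelme(scene: SceneTruth, label: str = "shoot") -> dict:
    """Serialize a scene as a LabelMe-dialect annotation document."""
    H, W = scene.image_size
    return {
        "imageHeight": H,
        "imageWidth": W,
        "shapes": [
            {"label": label, "points": [list(p) for p in mask_to_polygon(rec.mask)]}
            for rec, _, _ in scene.instances
        ],
    }


def write_scene(scene: SceneTruth, outdir: Path) -> dict[str, Path]:
    """Write a scene to disk: LabelMe JSON, labeled PNG (later instances on
    top in overlaps), and a truth CSV of picking points."""
    import json

    from PIL import Image

    from .io_formats import masks_to_label_image, write_pick_results

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["annotation"] = outdir / "scene.json"
    paths["annotation"].write_text(json.dumps(scene_to_labelme(scene)))
    label_img = masks_to_label_image([rec for rec, _, _ in scene.instances])
    if not scene.instances:
        H, W = scene.image_size
        label_img = np.zeros((H, W), dtype=np.uint16)
    paths["labels"] = outdir / "labels.png"
    Image.fromarray(label_img).save(paths["labels"])
    paths["truth"], paths["truth_json"] = write_pick_results(
        [(i, pick) for i, (_, _, pick) in enumerate(scene.instances)],
        outdir / "truth.csv")
    return paths
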