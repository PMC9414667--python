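import numpy as np
import pytest

from shootpick.io_formats import InstanceRecord, mask_to_box
from shootpick.synthetic_shoots import ShootSpec, generate_shoot


@pytest.fixture
def vertical_shoot():
    """A hole-free vertical capsule with exact ground truth."""
    spec = ShootSpec(length=100.0, width=12.0, axis_angle=90.0,
                     center=(100.0, 100.0), seed=7)
    mask, axis, pick = generate_shoot(spec, image_size=(200, 200))
    return spec, mask, axis, pick


def record_from_mask(mask: np.ndarray, score=None) -> InstanceRecord:
    return InstanceRecord(mask=mask, box=mask_to_box(mask), score=score)


@pytest.fixture
def record_factory():
    return record_from_mask


def random_convex_blob(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random filled convex polygon rasterized on a size x size grid."""
    from shootpick.io_formats import rasterize_polygon
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.uniform(4, size - 4, size=(12, 2))
        hull = ConvexHull(pts)
        poly = [tuple(p) for p in pts[hull.vertices]]
        mask = rasterize_polygon(poly, size, size)
        if mask.sum() >= 20:
            return mask
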