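import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_convex_blob, record_from_mask
from shootpick import picking_geometry as pg
from shootpick.synthetic_shoots import ShootSpec, generate_shoot


def component_of(mask):
    return pg.main_mask(pg.connected_components(mask))


class TestConnectedComponents:
    def test_solid_block_single_component(self):
        comps = pg.connected_components(np.ones((3, 3), dtype=bool))
        assert len(comps) == 1 and comps[0].area == 9

    @pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
    def test_diagonal_pixels_connectivity(self, connectivity, expected):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(pg.connected_components(mask, connectivity)) == expected

    def test_empty_mask_empty_list(self):
        assert pg.connected_components(np.zeros((3, 3), dtype=bool)) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_counts_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(123)
        for _ in range(40):
            mask = rng.random((32, 32)) < 0.35
            comps = pg.connected_components(mask, connectivity)
            oracle = oracles.flood_fill_components(mask, connectivity)
            assert len(comps) == len(oracle)
            assert sorted(c.area for c in comps) == sorted(len(s) for s in oracle)

    def test_areas_conserve_on_pixels(self):
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) < 0.4
        comps = pg.connected_components(mask)
        assert sum(c.area for c in comps) == mask.sum()
        assert all(a.area >= b.area for a, b in zip(comps, comps[1:]))


class TestMainMask:
    def test_selects_largest(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:1, 0:5] = True     # area 5
        mask[5:8, 5:8] = True     # area 9
        mask[15:16, 0:2] = True   # area 2
        assert component_of(mask).area == 9

    def test_single_component_identity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        comps = pg.connected_components(mask)
        assert pg.main_mask(comps) is comps[0]

    def test_area_tie_broken_by_topleft_pixel(self):
        mask = np.zeros((3, 10), dtype=bool)
        mask[0, 0:3] = True
        mask[0, 5:8] = True
        assert component_of(mask).min_pixel == (0, 0)

    def test_empty_list_raises(self):
        with pytest.raises(pg.EmptyMaskError):
            pg.main_mask([])


class TestMinAreaRect:
    def test_axis_aligned_block(self):
        mask = np.zeros((12, 6), dtype=bool)
        mask[0:10, 0:4] = True
        rect = pg.min_area_rect(component_of(mask))
        assert rect.long_side == pytest.approx(10.0)
        assert rect.short_side == pytest.approx(4.0)
        assert rect.long_axis_angle == pytest.approx(90.0)

    def test_single_pixel_is_unit_vertical_square(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        rect = pg.min_area_rect(component_of(mask))
        assert rect.long_side == pytest.approx(1.0)
        assert rect.short_side == pytest.approx(1.0)
        assert rect.long_axis_angle == 90.0

    def test_area_matches_orientation_sweep_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            comp = component_of(random_convex_blob(rng))
            rect = pg.min_area_rect(comp)
            rc = comp.pixels
            corners = np.concatenate([rc[:, ::-1] + off for off in
                                      ([0, 0], [1, 0], [0, 1], [1, 1])]).astype(float)
            oracle_area = oracles.min_rect_area_sweep(corners)
            assert rect.long_side * rect.short_side == pytest.approx(
                oracle_area, rel=1e-3)

    def test_rect_covers_all_pixel_squares(self):
        rng = np.random.default_rng(11)
        comp = component_of(random_convex_blob(rng))
        from shapely.geometry import Polygon, Point

        poly = Polygon(pg.min_area_rect(comp).corners()).buffer(1e-6)
        for r, c in comp.pixels[:: max(1, len(comp.pixels) // 50)]:
            for dx in (0, 1):
                for dy in (0, 1):
                    assert poly.covers(Point(c + dx, r + dy))

    def test_rotation_covariance(self):
        """Rotating the shoot rotates the recovered angle by the same amount."""
        base = 70.0
        mask0, _, _ = generate_shoot(ShootSpec(length=150, width=16, axis_angle=base,
                                               center=(200, 200)), (400, 400))
        a0 = pg.min_area_rect(component_of(mask0)).long_axis_angle
        for phi in (15.0, 30.0, 45.0):
            mask, _, _ = generate_shoot(ShootSpec(length=150, width=16,
                                                  axis_angle=base + phi,
                                                  center=(200, 200)), (400, 400))
            a = pg.min_area_rect(component_of(mask)).long_axis_angle
            delta = (a - a0) % 180.0
            assert abs(delta - phi) < 0.5


class TestShootAxis:
    def test_vertical_rect(self):
        rect = pg.MinAreaRect(center=(5, 10), long_side=20, short_side=4,
                              long_axis_angle=90.0)
        axis = pg.shoot_axis(rect)
        assert axis.bottom == pytest.approx((5, 20))
        assert axis.top == pytest.approx((5, 0))
        assert axis.theta == 90.0

    def test_45_degree_rect(self):
        rect = pg.MinAreaRect(center=(0.0, 0.0), long_side=2 * math.sqrt(2),
                              short_side=1.0, long_axis_angle=45.0)
        axis = pg.shoot_axis(rect)
        assert axis.bottom[1] > axis.top[1]
        assert axis.length == pytest.approx(2 * math.sqrt(2))
        assert axis.bottom == pytest.approx((-1.0, 1.0))
        assert axis.top == pytest.approx((1.0, -1.0))

    def test_horizontal_tie_bottom_has_larger_x(self):
        rect = pg.MinAreaRect(center=(10, 5), long_side=8, short_side=2,
                              long_axis_angle=0.0)
        axis = pg.shoot_axis(rect)
        assert axis.bottom == pytest.approx((14, 5))
        assert axis.top == pytest.approx((6, 5))

    def test_square_warns_and_uses_vertical(self, caplog):
        rect = pg.MinAreaRect(center=(0, 0), long_side=2, short_side=2,
                              long_axis_angle=90.0)
        with caplog.at_level("WARNING"):
            axis = pg.shoot_axis(rect)
        assert "ambiguous" in caplog.text
        assert axis.bottom[1] == pytest.approx(1.0)


class TestPickingPoint:
    def test_two_percent_up_vertical_axis(self):
        axis = pg.ShootAxis(bottom=(5, 100), top=(5, 0), theta=90.0)
        p = pg.picking_point(axis, 0.02)
        assert (p.x, p.y) == pytest.approx((5, 98))
        assert p.theta == 90.0

    @pytest.mark.parametrize("fraction,endpoint", [(0.0, "bottom"), (1.0, "top")])
    def test_boundary_fractions(self, fraction, endpoint):
        axis = pg.ShootAxis(bottom=(3, 30), top=(8, 2), theta=80.0)
        p = pg.picking_point(axis, fraction)
        assert (p.x, p.y) == pytest.approx(getattr(axis, endpoint))

    @pytest.mark.parametrize("fraction", [-0.1, 1.5])
    def test_fraction_out_of_range_rejected(self, fraction):
        axis = pg.ShootAxis(bottom=(0, 10), top=(0, 0), theta=90.0)
        with pytest.raises(ValueError):
            pg.picking_point(axis, fraction)


class TestLocate:
    def test_solid_vertical_instance(self):
        mask = np.zeros((110, 20), dtype=bool)
        mask[0:100, 5:15] = True
        (p,) = pg.locate([record_from_mask(mask)])
        assert (p.x, p.y) == pytest.approx((10.0, 98.0))
        assert p.theta == 90.0

    def test_fragment_ignored_in_favor_of_main_blob(self):
        mask = np.zeros((120, 40), dtype=bool)
        mask[5:105, 5:9] = True        # 400 px main blob
        mask[110:114, 30:33] = True    # 12 px fragment
        (p_full,) = pg.locate([record_from_mask(mask)])
        main_only = mask.copy()
        main_only[110:114, 30:33] = False
        (p_main,) = pg.locate([record_from_mask(main_only)])
        assert (p_full.x, p_full.y) == pytest.approx((p_main.x, p_main.y))
        assert p_full.theta == pytest.approx(p_main.theta)

    def test_empty_mask_skipped_with_warning(self, caplog):
        good = np.zeros((10, 10), dtype=bool)
        good[1:9, 4:6] = True

        class FakeRecord:
            mask = np.zeros((10, 10), dtype=bool)

        with caplog.at_level("WARNING"):
            pts = pg.locate([record_from_mask(good), FakeRecord()])
        assert len(pts) == 1
        assert "empty mask" in caplog.text

    def test_recovery_on_synthetic_shoots_seed1(self):
        """50 simulated shoots: axis within 1 degree, point within 2 px."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            spec = ShootSpec(length=rng.uniform(120, 260),
                             width=rng.uniform(12, 26),
                             axis_angle=rng.uniform(60, 120),
                             center=(756, 504), seed=int(rng.integers(2**31)))
            mask, _, pick = generate_shoot(spec)
            (p,) = pg.locate([record_from_mask(mask)])
            d = abs(p.theta - spec.axis_angle) % 180
            assert min(d, 180 - d) <= 1.0
            assert math.dist((p.x, p.y), (pick.x, pick.y)) <= 2.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30))
    def test_translation_equivariance(self, dx, dy):
        """Shifting the mask shifts the picking point by exactly the shift."""
        base = np.zeros((200, 200), dtype=bool)
        base[10:90, 20:32] = True
        base[12:20, 25:29] = False  # a hole, for variety
        shifted = np.zeros_like(base)
        shifted[10 + dy:90 + dy, 20 + dx:32 + dx] = True
        shifted[12 + dy:20 + dy, 25 + dx:29 + dx] = False
        (p0,) = pg.locate([record_from_mask(base)])
        (p1,) = pg.locate([record_from_mask(shifted)])
        assert (p1.x - p0.x, p1.y - p0.y) == pytest.approx((dx, dy), abs=1e-9)
        assert p1.theta == pytest.approx(p0.theta)

    def test_hole_filling_keeps_main_mask_choice(self):
        mask = np.zeros((60, 30), dtype=bool)
        mask[5:55, 5:20] = True
        mask[20:30, 8:15] = False  # hole
        filled = mask.copy()
        filled[20:30, 8:15] = True
        comp_holey = component_of(mask)
        comp_filled = component_of(filled)
        assert comp_holey.min_pixel == comp_filled.min_pixel
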