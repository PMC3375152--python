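"""Geometric substrate: region construction, arclength parametrization,
projection, rasterization, dilation, connected components."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from aacmorph import oracle as orc
from aacmorph.annotation import VertebraLandmarks, WallPolyline
from aacmorph.geometry import (
    RegionError,
    StructuringElement,
    build_aorta_region,
    canonicalize,
    connected_components,
    dilate,
    dilate_mask,
    dilate_polygons,
    param_wall,
    project_deposit_to_wall,
    rasterize,
)
from aacmorph.synthetic import gen_annotation

from conftest import make_straight_annotation, rect


class TestParamWall:
    def test_vertical_segment(self):
        assert param_wall(np.array([[0.0, 0.0], [0.0, 10.0]])).length == pytest.approx(10.0)

    def test_3_4_5_triangle(self):
        assert param_wall(np.array([[0.0, 0.0], [3.0, 4.0]])).length == pytest.approx(5.0)

    def test_random_polyline_matches_direct_sum(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.uniform(0.1, 1.0, size=(50, 2)), axis=0)
        wp = param_wall(pts)
        direct = sum(float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(49))
        assert wp.length == pytest.approx(direct, rel=1e-12)
        assert np.all(np.diff(wp.cumlen) > 0)

    def test_duplicate_point_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            param_wall(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


class TestAortaRegion:
    def test_rectangle_area(self):
        """Parallel vertical walls 6 mm apart over a 120 mm vertebral span
        enclose a 720 mm^2 region (and 240 mm^2 for a 40 mm span)."""
        a = make_straight_annotation(width=6.0)
        region = build_aorta_region(a.walls, a.vertebrae)
        assert region.area == pytest.approx(6.0 * 120.0, rel=1e-9)

        b = make_straight_annotation(width=6.0, heights=(10.0,) * 4)
        region_b = build_aorta_region(b.walls, b.vertebrae)
        assert region_b.area == pytest.approx(240.0, rel=1e-9)

    def test_equal_vertebrae_partition_walls_equally(self):
        a = make_straight_annotation(heights=(10.0,) * 4)
        region = build_aorta_region(a.walls, a.vertebrae)
        for section in region.sections:
            for side in ("anterior", "posterior"):
                lo, hi = section[side]
                assert hi - lo == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [2, 8, 21])
    def test_section_lengths_partition_wall(self, seed):
        a = canonicalize(gen_annotation(seed=seed))
        region = build_aorta_region(a.walls, a.vertebrae)
        for side in ("anterior", "posterior"):
            total = sum(s[side][1] - s[side][0] for s in region.sections)
            assert total == pytest.approx(region.walls[side].length, abs=1e-6)
            assert region.sections[0][side][0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 14])
    def test_curved_region_area_matches_raster(self, seed):
        a = canonicalize(gen_annotation(seed=seed))
        region = build_aorta_region(a.walls, a.vertebrae)
        ring = np.asarray(region.boundary.exterior.coords)
        frame = region.boundary.bounds
        grid = orc.raster_mask([ring], frame, 0.05)
        assert region.area == pytest.approx(orc.mask_area(grid, 0.05), rel=0.01)

    def test_crossing_walls_rejected(self):
        a = make_straight_annotation()
        crossed = a.walls["posterior"].points.copy()
        crossed[:, 0] = np.linspace(13.0, 1.0, len(crossed))  # crosses anterior
        a.walls["posterior"] = WallPolyline("posterior", crossed)
        with pytest.raises(RegionError):
            build_aorta_region(a.walls, a.vertebrae)

    def test_short_wall_rejected(self):
        a = make_straight_annotation()
        short = a.walls["anterior"].points
        a.walls["anterior"] = WallPolyline("anterior", short[short[:, 1] < 100.0])
        with pytest.raises(RegionError, match="cover"):
            build_aorta_region(a.walls, a.vertebrae)


class TestProjection:
    def test_square_flush_projects_its_side(self):
        a = make_straight_annotation()
        region = build_aorta_region(a.walls, a.vertebrae)
        ivs = project_deposit_to_wall(Polygon(rect(7.0, 40.0, 9.0, 42.0)),
                                      region.walls["anterior"])
        assert len(ivs) == 1
        lo, hi = ivs[0]
        assert (lo, hi) == (pytest.approx(40.0, abs=1e-9), pytest.approx(42.0, abs=1e-9))

    def test_deposit_cranial_of_wall_start_prunes_to_empty(self):
        a = make_straight_annotation()
        region = build_aorta_region(a.walls, a.vertebrae)
        ivs = project_deposit_to_wall(Polygon(rect(7.0, -4.0, 9.0, -2.0)),
                                      region.walls["anterior"])
        assert ivs == []

    def test_projection_total_never_exceeds_wall_length(self):
        for seed in (2, 3, 6):
            a = canonicalize(gen_annotation(seed=seed))
            region = build_aorta_region(a.walls, a.vertebrae)
            for side in ("anterior", "posterior"):
                wp = region.walls[side]
                for d in a.deposits:
                    total = sum(hi - lo for lo, hi in
                                project_deposit_to_wall(d, wp))
                    assert 0.0 <= total <= wp.length + 1e-9

    def test_curved_wall_interval_matches_raster_oracle(self):
        a = canonicalize(gen_annotation(seed=6))
        region = build_aorta_region(a.walls, a.vertebrae)
        ant, post = region.walls["anterior"], region.walls["posterior"]
        cover = {"anterior": 0.0, "posterior": 0.0}
        from aacmorph.geometry import project_deposits_to_walls, intervals_length
        ivs = project_deposits_to_walls([d.polygon for d in a.deposits], region)
        oracle = orc.wall_coverage_lengths([d.vertices for d in a.deposits],
                                           ant.points, post.points, 0.05)
        for side in ("anterior", "posterior"):
            assert intervals_length(ivs[side]) == pytest.approx(oracle[side], rel=0.02)


class TestRasterize:
    def test_known_square_area(self):
        mask = rasterize([Polygon(rect(0, 0, 10, 10))], (0, 0, 10, 10), 0.1)
        assert abs(mask.count - 10000) <= 10 / 0.1 * 4  # perimeter slack

    def test_empty_polygon_list(self):
        mask = rasterize([], (0, 0, 5, 5), 0.1)
        assert mask.count == 0

    def test_disjoint_squares_additive(self):
        s1, s2 = Polygon(rect(0, 0, 2, 2)), Polygon(rect(5, 5, 7, 7))
        frame = (0, 0, 8, 8)
        both = rasterize([s1, s2], frame, 0.05)
        assert both.count == (rasterize([s1], frame, 0.05).count
                              + rasterize([s2], frame, 0.05).count)

    def test_resource_guard(self):
        with pytest.raises(MemoryError):
            rasterize([], (0, 0, 1000, 1000), 0.0001)


class TestDilate:
    def test_radius_zero_is_identity(self):
        poly = Polygon(rect(3, 3, 6, 8))
        assert dilate_polygons(poly, StructuringElement(0.0)).area == poly.area

    def test_monotone_in_radius(self):
        poly = Polygon(rect(3, 3, 6, 8))
        areas = [dilate_polygons(poly, StructuringElement(r)).area
                 for r in (0.0, 1.0, 3.0, 8.92, 12.0)]
        assert all(a1 < a2 for a1, a2 in zip(areas, areas[1:]))
        assert all(dilate_polygons(poly, StructuringElement(r)).area >= poly.area
                   for r in (0.0, 2.0, 8.92))

    def test_point_deposit_dilates_to_disc(self):
        """An epsilon-square dilated by the study radius has ~pi r^2 area."""
        eps, r = 0.01, 8.92
        tiny = Polygon(rect(10 - eps / 2, 50 - eps / 2, 10 + eps / 2, 50 + eps / 2))
        area = dilate_polygons(tiny, StructuringElement(r)).area
        assert area == pytest.approx(np.pi * r * r, rel=0.02)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(-1.0)

    def test_mask_and_polygon_routes_agree(self):
        poly = Polygon(rect(4, 4, 7, 9))
        r = 2.0
        frame = (0, 0, 12, 14)
        mask = rasterize([poly], frame, 0.05)
        mask_area = dilate_mask(mask, StructuringElement(r)).area
        poly_area = dilate_polygons(poly, StructuringElement(r)).area
        assert mask_area == pytest.approx(poly_area, rel=0.01)

    def test_dispatch_on_deposit_lists(self):
        a = make_straight_annotation(deposits=[rect(7, 10, 9, 12)])
        footprint = dilate(a.deposits, StructuringElement(1.0))
        assert footprint.area > 4.0


@settings(deadline=None, derandomize=True, max_examples=20)
@given(r1=st.floats(0.0, 5.0), r2=st.floats(0.0, 5.0))
def test_dilation_monotone_property(r1, r2):
    """r1 <= r2 implies area(dilate(X, r1)) <= area(dilate(X, r2))."""
    r1, r2 = sorted((r1, r2))
    poly = Polygon(rect(2, 2, 5, 4))
    a1 = dilate_polygons(poly, StructuringElement(r1)).area
    a2 = dilate_polygons(poly, StructuringElement(r2)).area
    assert a1 <= a2 + 1e-9


class TestConnectedComponents:
    def test_disjoint_squares(self):
        comps = connected_components(
            [Polygon(rect(i * 5, 0, i * 5 + 2, 2)) for i in range(3)])
        assert len(comps) == 3

    def test_overlap_merges(self):
        comps = connected_components([
            Polygon(rect(0, 0, 2, 2)), Polygon(rect(1, 1, 3, 3)),
            Polygon(rect(10, 10, 12, 12)),
        ])
        assert sorted(len(c.members) for c in comps) == [1, 2]

    def test_touching_counts_as_one(self):
        comps = connected_components([Polygon(rect(0, 0, 2, 2)),
                                      Polygon(rect(2, 0, 4, 2))])
        assert len(comps) == 1

    def test_random_layout_matches_raster_labeling(self):
        rng = np.random.default_rng(11)
        polys = []
        for _ in range(30):
            # snap to a 0.1 mm lattice so gaps are either exact touches or
            # wider than the 0.05 mm raster cell
            cx, cy = np.round(rng.uniform(2, 38, size=2), 1)
            w, h = np.round(rng.uniform(0.5, 3.0, size=2), 1)
            polys.append(Polygon(rect(cx, cy, cx + w, cy + h)))
        comps = connected_components(polys)
        grid = orc.raster_mask([np.asarray(p.exterior.coords) for p in polys],
                               (0, 0, 45, 45), 0.05)
        assert len(comps) == orc.count_components(grid)
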