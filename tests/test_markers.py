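"""The seven calcification markers on constructed and random geometries."""

import numpy as np
import pytest

from aacmorph.geometry import StructuringElement, build_aorta_region, canonicalize
from aacmorph.markers import (
    MarkerConfig,
    compute_ac24,
    compute_area_pct,
    compute_ncd,
    compute_panel,
    compute_sim_area_pct,
    grade_fraction,
)
from aacmorph.synthetic import DepositSpec, gen_annotation

from conftest import make_straight_annotation, rect, rotate_annotation

XA, XP = 7.0, 13.0  # default wall x positions of the straight fixture


def anterior_patch(y0, y1):
    """Rectangle flush against the anterior wall (1 mm thick)."""
    return rect(XA, y0, XA + 1.0, y1)


def posterior_patch(y0, y1):
    return rect(XP - 1.0, y0, XP, y1)


class TestGradeRule:
    @pytest.mark.parametrize("f,expected", [
        (0.0, 0), (1e-12, 0), (0.2, 1), (0.3332, 1),
        (1.0 / 3.0, 2), (0.5, 2), (0.666, 2),
        (2.0 / 3.0, 3), (0.9, 3), (1.0, 3),
    ])
    def test_boundaries(self, f, expected):
        """Closed lower grade boundaries: exactly 1/3 grades 2, 2/3 grades 3."""
        assert grade_fraction(f) == expected


class TestAc24:
    def test_no_deposits_scores_zero(self, straight_annotation):
        assert compute_panel(straight_annotation).ac24 == 0

    def test_full_coverage_scores_24(self):
        a = make_straight_annotation(deposits=[rect(XA, 0.0, XP, 120.0)])
        assert compute_panel(a).ac24 == 24

    def test_half_of_one_section_scores_2(self):
        a = make_straight_annotation(deposits=[anterior_patch(0.0, 15.0)])
        assert compute_panel(a).ac24 == 2

    def test_exact_third_scores_2(self):
        a = make_straight_annotation(deposits=[anterior_patch(30.0, 40.0)])
        assert compute_panel(a).ac24 == 2

    def test_grades_sum_over_sections(self):
        a = make_straight_annotation(deposits=[
            anterior_patch(0.0, 6.0),        # L1 anterior: 0.2 -> 1
            posterior_patch(30.0, 57.0),     # L2 posterior: 0.9 -> 3
            anterior_patch(60.0, 75.0),      # L3 anterior: 0.5 -> 2
        ])
        assert compute_panel(a).ac24 == 6


class TestAreaMarkers:
    def test_deposit_equal_to_region_is_100(self):
        a = make_straight_annotation(deposits=[rect(XA, 0.0, XP, 120.0)])
        panel = compute_panel(a)
        assert panel.area_pct == pytest.approx(100.0, abs=1e-6)
        assert panel.sim_area_pct == pytest.approx(100.0, abs=1e-6)
        assert panel.thickness_pct == pytest.approx(100.0, abs=1e-6)
        assert panel.wall_pct == pytest.approx(100.0, abs=1e-6)
        assert panel.length_pct == pytest.approx(100.0, abs=1e-6)
        assert panel.ncd == 1

    def test_band_area_fraction(self):
        """A 1 mm band along a 6 mm lumen occupies 1/6 of the area."""
        a = make_straight_annotation(deposits=[anterior_patch(0.0, 120.0)])
        assert compute_panel(a).area_pct == pytest.approx(100.0 / 6.0, rel=1e-6)

    def test_sim_area_radius_zero_equals_area(self):
        a = make_straight_annotation(deposits=[anterior_patch(20.0, 50.0)])
        cfg = MarkerConfig(se_radius_mm=0.0)
        panel = compute_panel(a, cfg)
        assert panel.sim_area_pct == pytest.approx(panel.area_pct, rel=1e-9)

    def test_small_deposit_dilation_matches_disc_clip(self):
        """A 1 mm^2 deposit mid-region dilated by 8.92 mm covers the full
        lumen width, so the in-region simulated area is the chord area."""
        a = canonicalize(make_straight_annotation(
            deposits=[rect(9.5, 59.5, 10.5, 60.5)]))
        region = build_aorta_region(a.walls, a.vertebrae)
        got = compute_sim_area_pct(a, region, StructuringElement(8.92))
        from aacmorph import oracle as orc
        frame = (XA - 10, -10, XP + 10, 130.0)
        dep = orc.raster_mask([rect(9.5, 59.5, 10.5, 60.5)], frame, 0.05)
        reg = orc.raster_mask([np.asarray(region.boundary.exterior.coords)],
                              frame, 0.05)
        dil = orc.dilate_mask_edt(dep, 0.05, 8.92)
        expected = 100.0 * (dil & reg).sum() / reg.sum()
        assert got == pytest.approx(expected, rel=0.01)

    def test_sim_at_least_area_and_monotone_in_deposits(self):
        base = [anterior_patch(10.0, 14.0)]
        more = base + [posterior_patch(80.0, 90.0)]
        p1 = compute_panel(make_straight_annotation(deposits=base))
        p2 = compute_panel(make_straight_annotation(deposits=more))
        for p in (p1, p2):
            assert p.sim_area_pct >= p.area_pct
        assert p2.area_pct >= p1.area_pct
        assert p2.sim_area_pct >= p1.sim_area_pct


class TestThickness:
    def test_uniform_band(self):
        """Thickness t = 1 mm in a w = 5 mm lumen over the full length
        gives exactly 100 t / w = 20."""
        a = make_straight_annotation(
            width=5.0,
            deposits=[rect(10.0 - 2.5, 0.0, 10.0 - 1.5, 120.0)])
        assert compute_panel(a).thickness_pct == pytest.approx(20.0, rel=1e-6)

    def test_zero_without_deposits(self, straight_annotation):
        assert compute_panel(straight_annotation).thickness_pct == 0.0


class TestWallAndLength:
    def test_half_anterior_wall_is_25(self):
        a = make_straight_annotation(deposits=[anterior_patch(0.0, 60.0)])
        assert compute_panel(a).wall_pct == pytest.approx(25.0, rel=1e-6)

    def test_full_band_covers_one_wall(self):
        a = make_straight_annotation(deposits=[anterior_patch(0.0, 120.0)])
        panel = compute_panel(a)
        assert panel.wall_pct == pytest.approx(50.0, rel=1e-6)
        assert panel.length_pct == pytest.approx(100.0, rel=1e-6)

    def test_two_disjoint_quarters_give_50(self):
        a = make_straight_annotation(deposits=[
            anterior_patch(0.0, 30.0), posterior_patch(60.0, 90.0)])
        assert compute_panel(a).length_pct == pytest.approx(50.0, rel=1e-4)


class TestNcd:
    def test_counts_disjoint_deposits(self):
        deposits = [anterior_patch(10 + 20 * k, 14 + 20 * k) for k in range(5)]
        a = make_straight_annotation(deposits=deposits)
        assert compute_panel(a).ncd == 5

    def test_overlap_merges_and_out_of_region_excluded(self):
        a = make_straight_annotation(deposits=[
            anterior_patch(10.0, 14.0),
            anterior_patch(12.0, 16.0),        # overlaps the first
            anterior_patch(-20.0, -16.0),      # cranial of the region
        ])
        region = build_aorta_region(a.walls, a.vertebrae)
        assert compute_ncd(a, region) == 1

    def test_generated_disjoint_count(self):
        a = gen_annotation(dep=DepositSpec(count=5, min_separation_mm=1.0), seed=3)
        assert len(a.deposits) == 5
        assert compute_panel(a).ncd == 5


class TestPanel:
    def test_deposit_free_panel_is_all_zero(self, straight_annotation):
        panel = compute_panel(straight_annotation)
        assert all(v == 0 for v in panel.as_dict().values())

    def test_panel_composes_individual_markers(self):
        a = make_straight_annotation(deposits=[anterior_patch(5.0, 25.0)])
        panel = compute_panel(a)
        ac = canonicalize(a)
        region = build_aorta_region(ac.walls, ac.vertebrae)
        assert panel.ac24 == compute_ac24(ac, region)
        assert panel.area_pct == pytest.approx(compute_area_pct(ac, region))
        assert panel.ncd == compute_ncd(ac, region)

    def test_subdivision_invariance(self):
        """Splitting one deposit into two abutting halves with identical
        union changes no marker (NCD merges touching outlines)."""
        whole = make_straight_annotation(deposits=[anterior_patch(20.0, 40.0)])
        split = make_straight_annotation(deposits=[
            anterior_patch(20.0, 30.0), anterior_patch(30.0, 40.0)])
        p1, p2 = compute_panel(whole), compute_panel(split)
        for k, v in p1.as_dict().items():
            assert v == pytest.approx(p2.as_dict()[k], abs=1e-6), k

    @pytest.mark.parametrize("angle", [17.0, -35.0])
    def test_rigid_motion_invariance(self, angle):
        a = make_straight_annotation(deposits=[
            anterior_patch(5.0, 25.0), posterior_patch(70.0, 95.0)])
        b = rotate_annotation(a, angle)
        p1, p2 = compute_panel(a), compute_panel(b)
        for k, v in p1.as_dict().items():
            assert v == pytest.approx(p2.as_dict()[k], abs=1e-6), k

    @pytest.mark.parametrize("seed", [2, 6, 10])
    def test_random_panels_within_bounds(self, seed):
        panel = compute_panel(gen_annotation(seed=seed))
        assert 0 <= panel.ac24 <= 24
        for name in ("area_pct", "sim_area_pct", "thickness_pct",
                     "wall_pct", "length_pct"):
            assert 0.0 <= getattr(panel, name) <= 100.0
        assert panel.ncd >= 0
        assert panel.sim_area_pct >= panel.area_pct
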