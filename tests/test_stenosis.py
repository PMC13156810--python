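"""Geometric quantification: centerline, straightening, MLD/RVD, grading."""

import numpy as np
import pytest

from caroseg.image import LumenLabel
from caroseg.stenosis import (
    AreaProfile,
    area_profile,
    binarize_grade,
    equivalent_diameter,
    extract_centerline,
    find_mld,
    find_rvd,
    grade,
    nascet_percent,
    quantify,
    straighten,
)
from conftest import make_cylinder_mask, make_torus_mask, quant_spec


class TestExtractCenterline:
    def test_cylinder_centerline_close_to_analytic_axis(self):
        label, axis_rc = make_cylinder_mask()
        cl = extract_centerline(label)
        # all points within one voxel of the analytic axis (in-plane)
        d = np.sqrt((cl.points[:, 1] - axis_rc[0]) ** 2 + (cl.points[:, 2] - axis_rc[1]) ** 2)
        assert np.max(d) <= max(label.spacing)

    def test_y_phantom_has_three_branches_and_one_bifurcation(self, stenosed_phantom):
        _, label, _ = stenosed_phantom
        cl = extract_centerline(label)
        assert cl.branches == ["CCA", "ICA", "ECA"]
        assert cl.bifurcation_point is not None

    def test_ica_has_larger_radius_than_eca(self, stenosed_phantom):
        _, label, _ = stenosed_phantom
        cl = extract_centerline(label)
        med = {b: np.median(cl.radius[cl.branch == b]) for b in ("ICA", "ECA")}
        assert med["ICA"] > med["ECA"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(LumenLabel(np.zeros((8, 8, 8), np.uint8), (1, 1, 1)))

    def test_multiple_components_rejected(self):
        m = np.zeros((12, 12, 12), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        m[8:11, 8:11, 8:11] = 1
        with pytest.raises(ValueError, match="components"):
            extract_centerline(LumenLabel(m, (1, 1, 1)))

    def test_arclength_strictly_increasing_per_branch(self, stenosed_phantom):
        _, label, _ = stenosed_phantom
        cl = extract_centerline(label)
        for b in cl.branches:
            s, _ = cl.branch_path(b)
            assert np.all(np.diff(s) > 0)


class TestStraighten:
    def test_cylinder_planes_have_constant_area(self):
        label, _ = make_cylinder_mask(radius=3.0)
        cl = extract_centerline(label)
        sv = straighten(label, cl, step=0.5, plane_size=48, plane_spacing=0.3,
                        path_branches=("ICA",))
        prof = area_profile(sv)
        # skip skeleton end effects
        inner = prof.areas[3:-3]
        assert np.all(np.abs(inner - np.pi * 9) <= 0.1 * np.pi * 9)

    def test_curved_tube_profile_constant_after_straightening(self):
        label = make_torus_mask(tube_radius=3.0)
        cl = extract_centerline(label)
        sv = straighten(label, cl, step=0.5, plane_size=48, plane_spacing=0.3,
                        path_branches=("ICA",))
        prof = area_profile(sv, smooth_window=3)
        inner = prof.areas[4:-4]
        assert np.all(np.abs(inner - np.pi * 9) <= 0.1 * np.pi * 9)

    def test_step_larger_than_vessel_still_returns_planes(self):
        label, _ = make_cylinder_mask(shape=(20, 32, 32))
        cl = extract_centerline(label)
        sv = straighten(label, cl, step=500.0, path_branches=("ICA",))
        assert len(sv.planes) >= 1

    def test_non_positive_step_rejected(self):
        label, _ = make_cylinder_mask(shape=(20, 32, 32))
        cl = extract_centerline(label)
        with pytest.raises(ValueError):
            straighten(label, cl, step=0.0)

    def test_small_plane_auto_enlarged_once_with_warning(self):
        label, _ = make_cylinder_mask(radius=4.0)
        cl = extract_centerline(label)
        with pytest.warns(UserWarning, match="enlarging"):
            sv = straighten(label, cl, step=1.0, plane_size=16, plane_spacing=0.3,
                            path_branches=("ICA",))
        assert sv.planes.shape[1] == 32


class TestAreaProfileAndDiameter:
    def test_empty_plane_zero_area(self):
        from caroseg.stenosis import StraightenedVessel

        sv = StraightenedVessel(np.zeros((3, 8, 8), np.uint8), 0.5, 0.3,
                                np.array(["ICA"] * 3), np.arange(3) * 0.5)
        assert np.all(area_profile(sv).areas == 0.0)

    def test_hundred_pixels_at_point_three_grid(self):
        from caroseg.stenosis import StraightenedVessel

        planes = np.zeros((1, 20, 20), np.uint8)
        planes[0, :10, :10] = 1
        sv = StraightenedVessel(planes, 0.5, 0.3, np.array(["ICA"]), np.zeros(1))
        assert area_profile(sv).areas[0] == pytest.approx(9.0)

    def test_smoothing_window_one_is_identity(self, stenosed_phantom):
        _, label, _ = stenosed_phantom
        cl = extract_centerline(label)
        sv = straighten(label, cl, path_branches=("ICA",))
        assert np.array_equal(area_profile(sv, 1).areas, area_profile(sv).areas)

    def test_equivalent_diameter_values(self):
        assert equivalent_diameter(np.pi) == pytest.approx(2.0)
        assert equivalent_diameter(78.5398) == pytest.approx(10.0, abs=1e-4)
        assert equivalent_diameter(0.0) == 0.0
        with pytest.raises(ValueError):
            equivalent_diameter(-1.0)


class TestMldRvd:
    @staticmethod
    def _profile(areas, step=0.5):
        n = len(areas)
        return AreaProfile(np.asarray(areas, float), np.array(["ICA"] * n),
                           np.arange(n) * step, step)

    def test_tie_resolves_to_proximal_index(self):
        areas = [10, 10, 10, 10, 3, 10, 3, 10, 10, 10, 10, 10, 10, 10]
        i, _ = find_mld(self._profile(areas), guard_mm=1.0, end_guard_mm=1.0)
        assert i == 4

    def test_constant_vessel_mld_close_to_rvd(self):
        label, _ = make_cylinder_mask()
        rep, _ = quantify(label)
        assert rep.percent < 5.0
        assert rep.mld <= rep.rvd

    def test_missing_ica_rejected(self):
        prof = AreaProfile(np.ones(5), np.array(["CCA"] * 5), np.arange(5.0), 1.0)
        with pytest.raises(ValueError, match="ICA"):
            find_mld(prof)

    def test_bulb_max_strategy_picks_proximal_maximum(self):
        areas = [30, 28, 20, 10, 10, 10, 10, 10, 10, 10, 10, 10]
        prof = self._profile(areas, step=1.0)
        _, rvd_bulb = find_rvd(prof, "bulb_max", guard_mm=0.0, end_guard_mm=1.0)
        assert rvd_bulb == pytest.approx(equivalent_diameter(30))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            find_rvd(self._profile([1, 2, 3]), "nonsense")


class TestNascetAndGrades:
    def test_severe_boundary_example(self):
        assert nascet_percent(3.0, 10.0) == pytest.approx(70.0)

    def test_mild_boundary_example(self):
        assert nascet_percent(7.0, 10.0) == pytest.approx(30.0)

    def test_no_narrowing(self):
        assert nascet_percent(4.8, 4.8) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nascet_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            nascet_percent(5.0, 4.0)

    @pytest.mark.parametrize("pct,expected", [
        (10.0, "mild"), (30.0, "mild"), (30.001, "moderate"), (70.0, "moderate"),
        (70.001, "severe"), (85.0, "severe"),
    ])
    def test_grade_thresholds_closed_upper_intervals(self, pct, expected):
        assert grade(pct) == expected

    def test_grade_outside_open_interval_rejected(self):
        for bad in (0.0, 100.0, -5.0, 120.0):
            with pytest.raises(ValueError):
                grade(bad)

    def test_binarize_merges_mild_and_moderate(self):
        assert binarize_grade("mild") == "non-severe"
        assert binarize_grade("moderate") == "non-severe"
        assert binarize_grade("severe") == "severe"
        with pytest.raises(ValueError):
            binarize_grade("occluded")


class TestQuantify:
    def test_seventy_percent_phantom_recovered_within_five_points(self, stenosed_phantom):
        _, label, truth = stenosed_phantom
        rep, prof = quantify(label)
        assert abs(rep.percent - truth.primary_percent) <= 5.0
        assert rep.mld <= rep.rvd
        assert len(prof.areas) > 0

    def test_straightening_invariance_curved_vs_straight_tube(self):
        # congruent tubes: a straight cylinder and a quarter torus of the
        # same radius must quantify identically (percent within 2 points)
        straight, _ = make_cylinder_mask(shape=(56, 48, 48), radius=3.0)
        curved = make_torus_mask(tube_radius=3.0)
        p_straight = quantify(straight)[0].percent
        p_curved = quantify(curved)[0].percent
        assert abs(p_straight - p_curved) <= 2.0

    def test_report_fields_consistent(self, stenosed_phantom):
        _, label, _ = stenosed_phantom
        rep, _ = quantify(label)
        assert rep.percent == pytest.approx((1 - rep.mld / rep.rvd) * 100)
        assert rep.grade2 == binarize_grade(rep.grade3)
        d = rep.to_dict()
        assert set(d) >= {"mld_mm", "rvd_mm", "nascet_percent", "grade3", "grade2"}
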