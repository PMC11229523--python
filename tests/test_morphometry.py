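"""Tests for calibrated silhouette measurement and the reference formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitmorph import morphometry as mm
from fruitmorph import synthfruit
from fruitmorph.errors import DomainError, EmptyMaskError, SchemaError


class TestCalibration:
    def test_reference_ratios_are_self_consistent(self):
        # 0.126 px/mm and 0.016 px/mm^2 agree once squared (within 5%)
        cal = mm.CameraCalibration.from_pixel_ratios(px_per_mm=0.126, px_per_mm2=0.016)
        assert cal.mm_per_px == pytest.approx(1 / 0.126)

    def test_inconsistent_ratios_rejected(self):
        with pytest.raises(DomainError):
            mm.CameraCalibration(mm_per_px=0.25, mm2_per_px=0.1)

    def test_json_round_trip(self, tmp_path, calibration):
        path = tmp_path / "cal.json"
        calibration.to_json(path)
        assert mm.CameraCalibration.from_json(path) == calibration


class TestCountsAndAreas:
    def test_empty_and_full_masks(self):
        assert mm.count_foreground(np.zeros((5, 5), dtype=np.uint8)) == 0
        assert mm.count_foreground(np.ones((20, 30), dtype=np.uint8)) == 600

    def test_disc_count_matches_bruteforce_membership(self):
        spec = synthfruit.FruitImageSpec(semi_axes_px=(50.0, 50.0), canvas=(130, 130))
        mask, _ = synthfruit.render_binary_ellipse(spec)
        count = mm.count_foreground(mask)
        # brute-force membership over the grid is the exact oracle
        yy, xx = np.mgrid[0:130, 0:130]
        inside = ((yy - 64.5) ** 2 + (xx - 64.5) ** 2) <= 50.0**2
        assert count == inside.sum()
        assert abs(count - math.pi * 50.0**2) <= 2 * math.pi * 50 + 2

    def test_area_unit_conversion(self, calibration):
        assert mm.area_cm2(0, calibration) == 0.0
        cal = mm.CameraCalibration(mm_per_px=1.0, mm2_per_px=1.0)
        assert mm.area_cm2(10000, cal) == pytest.approx(100.0)

    def test_area_with_reference_scale_ratio(self):
        cal = mm.CameraCalibration(mm_per_px=math.sqrt(0.0158), mm2_per_px=0.0158)
        assert mm.area_cm2(7854, cal) == pytest.approx(7854 * 0.0158 / 100)


class TestChords:
    def test_single_row_run(self):
        mask = np.zeros((3, 30), dtype=np.uint8)
        mask[1, 5:22] = 1
        assert mm.max_chord(mask) == 17

    def test_axis_aligned_ellipse_chord(self):
        spec = synthfruit.FruitImageSpec(semi_axes_px=(80.0, 50.0), pose_deg=0.0)
        mask, _ = synthfruit.render_binary_ellipse(spec)
        assert abs(mm.max_chord(mask) - 160) <= 2
        rotated = mm.rotate_mask(mask, 90)
        assert abs(mm.max_chord(rotated) - 100) <= 2

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mm.max_chord(np.zeros((4, 4), dtype=np.uint8))

    def test_run_split_by_hole(self):
        mask = np.zeros((1, 11), dtype=np.uint8)
        mask[0, :] = 1
        mask[0, 5] = 0
        assert mm.max_chord(mask) == 5


class TestRotation:
    def test_zero_angle_identity(self, ellipse_mask):
        mask, _ = ellipse_mask
        np.testing.assert_array_equal(mm.rotate_mask(mask, 0), mask)

    def test_180_twice_restores_foreground(self, ellipse_mask):
        mask, _ = ellipse_mask
        twice = mm.rotate_mask(mm.rotate_mask(mask, 180), 180)
        assert twice.sum() == mask.sum()
        # involution up to canvas offset: crop both to bounding boxes
        def bbox(m):
            rr, cc = np.nonzero(m)
            return m[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]

        np.testing.assert_array_equal(bbox(twice), bbox(mask))

    @pytest.mark.parametrize("angle", [17.0, 45.0, 121.5])
    def test_area_nearly_preserved(self, ellipse_mask, angle):
        mask, _ = ellipse_mask
        rotated = mm.rotate_mask(mask, angle)
        assert abs(int(rotated.sum()) - int(mask.sum())) / mask.sum() < 0.01


class TestMeasureAxes:
    def test_circle_is_pose_free(self, calibration):
        spec = synthfruit.FruitImageSpec(semi_axes_px=(40.0, 40.0), canvas=(120, 120))
        mask, _ = synthfruit.render_binary_ellipse(spec)
        axes = mm.measure_axes(mask, calibration, step_deg=5.0)
        assert abs(axes.L1_px - 80) <= 2
        assert abs(axes.L3_px - 80) <= 2

    def test_rotated_ellipse_recovers_both_axes(self, calibration):
        spec = synthfruit.FruitImageSpec(semi_axes_px=(80.0, 50.0), pose_deg=37.0)
        mask, _ = synthfruit.render_binary_ellipse(spec)
        axes = mm.measure_axes(mask, calibration, step_deg=1.0)
        assert abs(axes.L1_px - 160) <= 2
        assert abs(axes.L3_px - 100) <= 2
        assert axes.a_mm == pytest.approx(axes.L1_px * 0.25 / 2)
        assert axes.b_mm == pytest.approx(axes.L3_px * 0.25 / 2)

    def test_pose_invariance(self, calibration):
        results = []
        for pose in (0.0, 63.0):
            spec = synthfruit.FruitImageSpec(semi_axes_px=(80.0, 50.0), pose_deg=pose)
            mask, _ = synthfruit.render_binary_ellipse(spec)
            results.append(mm.measure_axes(mask, calibration, step_deg=1.0))
        assert abs(results[0].L1_px - results[1].L1_px) <= 2
        assert abs(results[0].L3_px - results[1].L3_px) <= 2

    def test_translation_invariance(self, calibration):
        canvas = (260, 260)
        at_center = synthfruit.FruitImageSpec(
            semi_axes_px=(60.0, 40.0), pose_deg=20.0, canvas=canvas
        )
        shifted = synthfruit.FruitImageSpec(
            semi_axes_px=(60.0, 40.0), pose_deg=20.0, canvas=canvas, center=(100.0, 150.0)
        )
        m1, _ = synthfruit.render_binary_ellipse(at_center)
        m2, _ = synthfruit.render_binary_ellipse(shifted)
        a1 = mm.measure_axes(m1, calibration, step_deg=3.0)
        a2 = mm.measure_axes(m2, calibration, step_deg=3.0)
        assert abs(a1.L1_px - a2.L1_px) <= 2
        assert abs(a1.L3_px - a2.L3_px) <= 2


class TestScalars:
    def test_cpa_reference_means(self):
        # mean projected areas of the reference dataset -> printed mean CPA
        assert mm.compute_cpa(9.49, 9.37, 12.24) == pytest.approx(10.37, abs=0.005)

    def test_cpa_identities(self):
        assert mm.compute_cpa(0, 0, 0) == 0
        assert mm.compute_cpa(3.3, 3.3, 3.3) == pytest.approx(3.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pas=st.tuples(
            *[st.floats(0.1, 100, allow_nan=False) for _ in range(3)]
        )
    )
    def test_cpa_bounded_by_extremes(self, pas):
        cpa = mm.compute_cpa(*pas)
        assert min(pas) <= cpa + 1e-12 and cpa <= max(pas) + 1e-12

    def test_slice_integrate_full_circle(self):
        profile = [(10.0, 2.0)] * 36
        assert mm.slice_integrate_area(profile) == pytest.approx(4 * math.pi)
        assert mm.slice_integrate_area([(360.0, 1.0)]) == pytest.approx(math.pi)

    def test_slice_integrate_hand_summed_sectors(self):
        profile = [(90.0, 1.0), (90.0, 2.0), (90.0, 1.0), (90.0, 2.0)]
        assert mm.slice_integrate_area(profile) == pytest.approx(2.5 * math.pi)

    def test_slice_integrate_refinement_invariance(self):
        base = [(120.0, 1.5), (120.0, 2.5), (120.0, 1.0)]
        refined = [(60.0, 1.5), (60.0, 1.5), (120.0, 2.5), (120.0, 1.0)]
        assert mm.slice_integrate_area(base) == pytest.approx(
            mm.slice_integrate_area(refined)
        )

    def test_slice_integrate_open_profile_rejected(self):
        with pytest.raises(DomainError):
            mm.slice_integrate_area([(90.0, 1.0)] * 3)

    def test_mre_basics(self):
        assert mm.mean_relative_error([5.0, 7.0], [5.0, 7.0]) == 0.0
        assert mm.mean_relative_error([102, 98], [100, 100]) == pytest.approx(2.0)

    def test_mre_matches_explicit_loop(self, rng):
        pv = rng.uniform(5, 20, 16)
        mv = rng.uniform(5, 20, 16)
        expected = sum(abs(p - m) / m for p, m in zip(pv, mv)) / 16 * 100
        assert mm.mean_relative_error(pv, mv) == pytest.approx(expected, abs=1e-12)

    def test_mre_domain_errors(self):
        with pytest.raises(DomainError):
            mm.mean_relative_error([1.0], [1.0, 2.0])
        with pytest.raises(DomainError):
            mm.mean_relative_error([1.0], [0.0])


class TestGeometricVolumes:
    def test_unit_sphere(self):
        assert mm.ellipsoid_volume(1, 1) == pytest.approx(4 * math.pi / 3)
        assert mm.paraboloid_volume(1, 1) == pytest.approx(4 * math.pi / 3)

    def test_reference_mean_axes(self):
        # evaluated at the reference dataset's mean half-axes (cm)
        assert mm.ellipsoid_volume(1.972, 1.476) == pytest.approx(24.043, abs=0.001)
        assert mm.paraboloid_volume(1.972, 1.476) == pytest.approx(17.996, abs=0.001)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.5, 5, allow_nan=False), b=st.floats(0.5, 5, allow_nan=False)
    )
    def test_scaling_and_ratio_identities(self, a, b):
        assert mm.ellipsoid_volume(2 * a, b) == pytest.approx(4 * mm.ellipsoid_volume(a, b))
        assert mm.ellipsoid_volume(a, 2 * b) == pytest.approx(2 * mm.ellipsoid_volume(a, b))
        assert mm.paraboloid_volume(a, b) / mm.ellipsoid_volume(a, b) == pytest.approx(b / a)

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(DomainError):
            mm.ellipsoid_volume(-1, 1)
        with pytest.raises(DomainError):
            mm.paraboloid_volume(1, 0)


class TestMeasureFruit:
    def test_three_identical_discs(self, calibration):
        spec = synthfruit.FruitImageSpec(semi_axes_px=(40.0, 40.0), canvas=(120, 120))
        mask, _ = synthfruit.render_binary_ellipse(spec)
        rec = mm.measure_fruit({"x": mask, "y": mask, "z": mask}, calibration, 5.0)
        assert rec.pa1_cm2 == rec.pa2_cm2 == rec.pa3_cm2
        assert rec.cpa_cm2 == pytest.approx(rec.pa1_cm2)
        assert rec.a_mm == pytest.approx(10.0, abs=0.3)
        assert rec.b_mm == pytest.approx(10.0, abs=0.3)

    def test_triaxial_projections_match_analytic(self, calibration):
        p, q, r = 20.0, 17.0, 13.0  # mm
        specs = synthfruit.make_three_views((p, q, r), calibration.mm_per_px)
        masks = {v: synthfruit.render_binary_ellipse(s)[0] for v, s in specs.items()}
        rec = mm.measure_fruit(masks, calibration, 1.0)
        assert rec.pa1_cm2 == pytest.approx(math.pi * q * r / 100, rel=0.03)
        assert rec.pa2_cm2 == pytest.approx(math.pi * p * r / 100, rel=0.03)
        assert rec.pa3_cm2 == pytest.approx(math.pi * p * q / 100, rel=0.03)
        assert rec.a_mm == pytest.approx(p, rel=0.03)
        assert rec.b_mm == pytest.approx(r, rel=0.03)
        assert rec.v_ellip_ml == pytest.approx(
            mm.ellipsoid_volume(rec.a_mm / 10, rec.b_mm / 10)
        )

    def test_empty_view_error_names_view(self, calibration, ellipse_mask):
        mask, _ = ellipse_mask
        empty = np.zeros_like(mask)
        with pytest.raises(EmptyMaskError, match="'y'"):
            mm.measure_fruit({"x": mask, "y": empty, "z": mask}, calibration, 5.0)


class TestRecordIO:
    def test_csv_round_trip_with_missing_values(self, tmp_path):
        recs = [
            mm.FruitRecord(
                id="f1", mass_g=18.0, volume_ml=17.5, a_mm=19.7, b_mm=14.8,
                pa1_cm2=9.5, pa2_cm2=9.4, pa3_cm2=12.2, cpa_cm2=10.4,
                v_ellip_ml=24.0, v_parab_ml=18.0,
            ),
            mm.FruitRecord(id="f2", pa3_cm2=11.0),
        ]
        path = tmp_path / "records.csv"
        mm.records_to_csv(recs, path)
        back = mm.read_records_csv(path)
        assert back[0].mass_g == pytest.approx(18.0)
        assert back[1].mass_g is None
        assert back[1].pa3_cm2 == pytest.approx(11.0)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,mass_g\nf1,10\n")
        with pytest.raises(SchemaError):
            mm.read_records_csv(path)
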