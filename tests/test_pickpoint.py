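"""Picking-point localization: intersection, tracing, fitting, calibration."""

import numpy as np
import pytest

from teapick import pickpoint, scene
from teapick.pickpoint import (
    CameraCalibration,
    DetectionBox,
    LocateConfig,
    StemTrace,
    blade_displacement,
    find_intersection,
    fit_growth_curve,
    locate_all,
    locate_pick_point_px,
    pixel_to_world,
    trace_stem,
    world_to_pixel,
)


def make_skeleton(shape, strokes):
    skel = np.zeros(shape, dtype=np.uint8)
    for r, c in strokes:
        skel[r, c] = 1
    return skel


def y_skeleton(shape=(60, 41), junction=(20, 20)):
    """Single bud line, a junction, two leaf branches and a stem below."""
    jr, jc = junction
    skel = np.zeros(shape, dtype=np.uint8)
    skel[5:jr + 1, jc] = 1                       # bud line down to junction
    skel[jr:, jc] = 1                            # stem straight down
    for k in range(1, 12):                       # leaves diverge downward
        skel[jr + k, jc - k] = 1
        skel[jr + k, jc + k] = 1
    return skel


class TestFindIntersection:
    def test_junction_row_found_on_y_shape(self):
        skel = y_skeleton()
        box = DetectionBox(0, 0, 0, 41, 60)
        (r, c), flags = find_intersection(skel, box)
        assert abs(r - 21) <= 1   # first doubled row is just below the junction
        assert abs(c - 20) <= 1
        assert flags == []

    def test_single_vertical_line_falls_back_flagged(self):
        skel = make_skeleton((30, 11), [(r, 5) for r in range(4, 26)])
        box = DetectionBox(0, 0, 0, 11, 30)
        (r, c), flags = find_intersection(skel, box)
        assert (r, c) == (25, 5)
        assert "no_junction" in flags

    def test_empty_box_rejected(self):
        skel = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="no skeleton"):
            find_intersection(skel, DetectionBox(0, 0, 0, 10, 10))

    def test_synthetic_shoot_junction_near_true_tip(self, default_scene):
        """End-to-end: detected intersection lands within ~1 mm of the tip."""
        from teapick.skeleton import binarize, thin

        truth, rendered = default_scene
        ppm = rendered.px_per_mm
        for shoot, box in zip(truth.shoots, rendered.boxes):
            crop = rendered.image[box.z_min:box.z_max, box.x_min:box.x_max]
            skel = thin(binarize(crop))
            local = DetectionBox(0, 0, 0, box.width, box.height)
            (r, c), _ = find_intersection(skel, local)
            tip_row = shoot.tip[1] * ppm - box.z_min
            tip_col = shoot.tip[0] * ppm - box.x_min
            assert abs(r - tip_row) <= 10   # 2 mm at 5 px/mm
            assert abs(c - tip_col) <= 5


class TestTraceStem:
    def test_straight_vertical_skeleton(self):
        skel = make_skeleton((60, 11), [(r, 5) for r in range(5, 55)])
        box = DetectionBox(0, 0, 0, 11, 60)
        trace = trace_stem(skel, (5, 5), box)
        assert len(trace.path) == 50
        assert np.all(trace.path[:, 1] == 5)
        assert trace.arc_length_px == pytest.approx(49.0)

    def test_junction_follows_deep_stem_not_leaf(self):
        skel = y_skeleton()
        box = DetectionBox(0, 0, 0, 41, 60)
        trace = trace_stem(skel, (20, 20), box)
        # stem reaches the box bottom; a leaf branch would stop at row 31
        assert trace.path[-1][0] == 59
        assert np.all(trace.path[trace.path[:, 0] > 35, 1] == 20)

    def test_bowed_synthetic_stem_tracks_centerline(self, default_scene):
        from teapick.skeleton import binarize, thin

        truth, rendered = default_scene
        ppm = rendered.px_per_mm
        shoot, box = truth.shoots[0], rendered.boxes[0]
        crop = rendered.image[box.z_min:box.z_max, box.x_min:box.x_max]
        skel = thin(binarize(crop))
        local = DetectionBox(0, 0, 0, box.width, box.height)
        start, _ = find_intersection(skel, local)
        trace = trace_stem(skel, start, local)
        poly = shoot.stem_polyline
        # compare trace columns with the generator centerline, below the
        # leaf region (first 60 px) where the skeleton is pure stalk
        for r, c in trace.path[60:]:
            z_mm = (r + box.z_min + 0.5) / ppm
            if z_mm >= poly[-1, 1]:
                break
            x_true_px = np.interp(z_mm, poly[:, 1], poly[:, 0]) * ppm - 0.5
            assert abs(c - (x_true_px - box.x_min)) <= 1.5

    def test_dead_end_start_flags_short_trace(self):
        skel = make_skeleton((10, 5), [(2, 2)])
        box = DetectionBox(0, 0, 0, 5, 10)
        trace = trace_stem(skel, (2, 2), box)
        assert "short_trace" in trace.flags

    def test_start_off_skeleton_rejected(self):
        skel = np.zeros((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError):
            trace_stem(skel, (2, 2), DetectionBox(0, 0, 0, 5, 5))


class TestFitGrowthCurve:
    def test_vertical_trace_collapses_to_constant(self):
        path = np.array([(r, 7) for r in range(10)])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=9.0))
        assert curve.degree == 0
        assert curve(4.5) == pytest.approx(7.0)

    def test_exact_quadratic_interpolated(self):
        rows = np.arange(30.0)
        cols = 5.0 + 0.01 * (rows - 3.0) ** 2
        path = np.column_stack([rows, cols])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=0.0), degree=2)
        assert curve.fit_residual < 1e-6

    def test_noisy_quadratic_residual_bounded(self):
        rng = np.random.default_rng(0)
        rows = np.arange(200.0)
        cols = 40.0 + 0.001 * rows**2 + rng.normal(0, 0.5, rows.shape)
        curve = fit_growth_curve(
            StemTrace(path=np.column_stack([rows, cols]), arc_length_px=0.0), degree=2
        )
        assert curve.fit_residual < 1.5  # 3 sigma

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_curve(StemTrace(path=np.array([[0, 0]]), arc_length_px=0.0))


class TestOffsetAndCalibration:
    calib = CameraCalibration(Ht=980)

    def test_default_offset_is_twenty_pixels(self):
        # 4 mm * 980 px / 196 mm = 20 px
        path = np.array([(r, 10) for r in range(100)])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=99.0))
        (row, col), flags = locate_pick_point_px(curve, (30, 10), 4.0, self.calib)
        assert row == pytest.approx(50.0)
        assert col == pytest.approx(10.0)
        assert flags == []

    def test_zero_offset_returns_start(self):
        path = np.array([(r, 10) for r in range(100)])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=99.0))
        (row, col), _ = locate_pick_point_px(curve, (30, 10), 0.0, self.calib)
        assert row == pytest.approx(30.0) and col == pytest.approx(10.0)

    def test_offset_monotone_in_depth(self):
        path = np.array([(r, 10 + 0.01 * r) for r in range(300)])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=0.0))
        zs = []
        for offset in (1.0, 2.0, 4.0, 8.0):
            (row, _), _ = locate_pick_point_px(curve, (10, 10), offset, self.calib)
            zs.append(pixel_to_world((0, row), self.calib)[1])
        assert np.all(np.diff(zs) > 0)

    def test_offset_beyond_curve_clamped_and_flagged(self):
        path = np.array([(r, 10) for r in range(10)])
        curve = fit_growth_curve(StemTrace(path=path, arc_length_px=9.0))
        (row, _), flags = locate_pick_point_px(curve, (5, 10), 4.0, self.calib)
        assert row == 9.0
        assert "offset_clamped" in flags

    def test_pixel_to_world_proportionality(self):
        assert pixel_to_world((0, 0), self.calib) == (0.0, 0.0)
        assert pixel_to_world((0, 980), self.calib)[1] == pytest.approx(196.0)
        assert pixel_to_world((0, 490), self.calib)[1] == pytest.approx(98.0)

    def test_pixel_world_round_trip_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pt = (float(rng.uniform(0, 1500)), float(rng.uniform(0, 980)))
            back = world_to_pixel(pixel_to_world(pt, self.calib), self.calib)
            assert np.allclose(back, pt, atol=1e-9)

    def test_pixel_to_world_is_linear(self):
        a = np.array(pixel_to_world((100.0, 200.0), self.calib))
        b = np.array(pixel_to_world((40.0, 60.0), self.calib))
        combo = np.array(pixel_to_world((100.0 + 2 * 40.0, 200.0 + 2 * 60.0), self.calib))
        assert np.allclose(combo, a + 2 * b, atol=1e-12)

    def test_blade_displacement(self):
        assert blade_displacement(0.0, self.calib) == pytest.approx(16.0)
        assert blade_displacement(40.0, self.calib, z_prev_mm=40.0) == 0.0
        assert blade_displacement(100.0, self.calib, z_prev_mm=40.0) == pytest.approx(60.0)
        with pytest.raises(ValueError):
            blade_displacement(300.0, self.calib)


class TestLocateAll:
    def test_three_shoots_within_three_millimetres(self, default_scene):
        truth, rendered = default_scene
        calib = CameraCalibration(Ht=rendered.image_height_Ht)
        result = locate_all(rendered.image, rendered.boxes, calib)
        assert len(result.points) == 3
        assert result.skipped == []
        for p, shoot in zip(result.points, truth.shoots):
            err = np.linalg.norm(np.array(p.world) - shoot.true_pick_point)
            assert err <= 3.0

    def test_empty_box_list(self, default_scene):
        _, rendered = default_scene
        result = locate_all(rendered.image, [])
        assert result.points == [] and result.skipped == []

    def test_fov_filter_skips_off_center_boxes(self, default_scene):
        _, rendered = default_scene
        cfg = LocateConfig(fov_width_px=10)   # tiny central strip
        result = locate_all(rendered.image, rendered.boxes, config=cfg)
        assert result.points == []
        assert all(reason == "outside_field_of_view" for _, reason in result.skipped)
        assert len(result.skipped) == len(rendered.boxes)

    def test_calibration_image_mismatch_rejected(self, default_scene):
        _, rendered = default_scene
        with pytest.raises(ValueError, match="Ht"):
            locate_all(rendered.image, rendered.boxes, CameraCalibration(Ht=100))

    def test_vertical_shoot_offset_is_four_millimetres(self):
        """On a perfectly vertical shoot the intersection-to-pick-point
        world drop equals the 4 mm offset to within one pixel pitch."""
        cfg = scene.GeneratorConfig()
        cfg.ranges = dict(cfg.ranges, curvature_amplitude_mm=(0.0, 0.0))
        truth = scene.build_scene(1, cfg, rng=1)
        rendered = scene.render(truth)
        calib = CameraCalibration(Ht=rendered.image_height_Ht)
        result = locate_all(rendered.image, rendered.boxes, calib)
        (p,) = result.points
        drop = p.world[1] - p.intersection_world[1]
        assert drop == pytest.approx(4.0, abs=0.2)
        assert p.world[0] == pytest.approx(p.intersection_world[0], abs=0.4)
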