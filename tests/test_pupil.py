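"""Pupil segmentation and landmark ellipse fitting."""

import numpy as np
import pytest

from chophot.pupil import (
    SegmentationParams,
    _filter_edge_pixels,
    area_equivalent_diameter,
    fit_pupil_from_landmarks,
    preprocess_pupil_trace,
    segment_pupil_frame,
)
from chophot.synth import render_eye_frame
from chophot.traces import PupilTrace


class TestSegmentFrame:
    def test_ideal_circle_recovered(self):
        img, truth = render_eye_frame(40.0, (80, 60), seed=1)
        _, d, ok = segment_pupil_frame(img)
        assert ok
        assert abs(d - truth) < 0.01 * truth

    def test_ellipse_area_equivalent_diameter(self):
        # semi-axes (20, 14) -> area-equivalent diameter 2*sqrt(20*14)
        target = 2 * np.sqrt(20 * 14)
        img, truth = render_eye_frame(target, (80, 60), eccentricity=40 / 28, seed=2)
        _, d, ok = segment_pupil_frame(img)
        assert ok
        assert abs(d - target) < 0.02 * target

    def test_specular_highlight_tolerated(self):
        rf = np.sqrt(0.05) / 2  # blob covering 5% of pupil area
        img, truth = render_eye_frame(
            40.0, (80, 60), eccentricity=1.5, highlight_spec=[(0.03, 0.02, rf)], seed=3
        )
        _, d, ok = segment_pupil_frame(img)
        assert ok
        assert abs(d - truth) < 0.02 * truth

    def test_eyelid_occlusion_tolerated(self):
        img, truth = render_eye_frame(40.0, (80, 60), occlusion_frac=0.2, seed=4)
        _, d, ok = segment_pupil_frame(img)
        assert ok
        assert abs(d - truth) < 0.05 * truth

    def test_blank_frame_rejected(self):
        with pytest.raises(ValueError, match="pupil"):
            segment_pupil_frame(
                np.full((40, 40), 200.0), SegmentationParams(intensity_threshold=10)
            )

    def test_rotation_invariance(self):
        img, truth = render_eye_frame(35.0, (80, 60), eccentricity=1.3, seed=5)
        _, d0, _ = segment_pupil_frame(img)
        _, d90, _ = segment_pupil_frame(np.rot90(img).copy())
        assert abs(d90 - d0) < 0.01 * d0

    def test_monotone_in_true_diameter(self):
        diams = [10, 20, 30, 40, 50, 60]
        rec = []
        for i, d in enumerate(diams):
            img, _ = render_eye_frame(float(d), (80, 60), seed=10 + i)
            rec.append(segment_pupil_frame(img)[1])
        assert np.all(np.diff(rec) > 0)


class TestEdgeFilters:
    def test_distant_edge_pixel_excluded(self):
        # pupil pixel block; an edge pixel 4 px away violates the 3 px rule
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:12, 8:12] = True
        edges = np.array([[10, 15], [10, 13]])  # distances 4 and 2 from mask
        kept = _filter_edge_pixels(
            edges, mask, (10.0, 10.0), 10.0, SegmentationParams()
        )
        assert kept.tolist() == [[10, 13]]

    def test_annulus_bounds_radial_distance(self):
        mask = np.ones((40, 40), dtype=bool)  # proximity always satisfied
        center = (20.0, 20.0)
        D = 16.0  # annulus radii [4, 14]
        edges = np.array([[20, 23], [20, 26], [20, 35]])  # r = 3, 6, 15
        kept = _filter_edge_pixels(edges, mask, center, D, SegmentationParams())
        assert kept.tolist() == [[20, 26]]


class TestLandmarks:
    @staticmethod
    def _ellipse_points(a, b, n=8, center=(0.0, 0.0)):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.c_[center[0] + a * np.cos(t), center[1] + b * np.sin(t)]

    def test_exact_circle(self):
        pts = self._ellipse_points(20, 20)
        _, d, ok = fit_pupil_from_landmarks(pts, np.ones(8))
        assert ok
        assert d == pytest.approx(40.0, abs=1e-6)

    def test_low_confidence_point_dropped(self):
        pts = self._ellipse_points(20, 14)
        conf = np.ones(8)
        conf[3] = 0.5
        pts[3] = (999.0, 999.0)  # would wreck the fit if not dropped
        _, d, ok = fit_pupil_from_landmarks(pts, conf)
        assert ok
        assert d == pytest.approx(40.0, rel=0.01)  # long axis, not area-equivalent

    def test_under_determined_invalid(self):
        pts = self._ellipse_points(20, 14)
        conf = np.array([1, 1, 1, 1, 0.1, 0.1, 0.1, 0.1])
        _, d, ok = fit_pupil_from_landmarks(pts, conf)
        assert not ok and np.isnan(d)

    def test_area_equivalent_not_larger_than_long_axis(self):
        pts = self._ellipse_points(20, 14, n=16)
        _, d_long, _ = fit_pupil_from_landmarks(pts, np.ones(16))
        d_area = area_equivalent_diameter(20, 14)
        assert d_area <= d_long + 1e-9
        # equality for a circle
        pts_c = self._ellipse_points(15, 15, n=16)
        _, d_long_c, _ = fit_pupil_from_landmarks(pts_c, np.ones(16))
        assert d_long_c == pytest.approx(area_equivalent_diameter(15, 15), abs=1e-6)


class TestPreprocessTrace:
    def test_all_valid_identity(self):
        tr = PupilTrace(fs=30.0, diameter=np.array([10.0, 11.0, 12.0]))
        out = preprocess_pupil_trace(tr)
        assert np.array_equal(out.diameter, tr.diameter)

    def test_single_gap_linear_midpoint(self):
        tr = PupilTrace(
            fs=30.0,
            diameter=np.array([10.0, np.nan, 12.0]),
            valid=np.array([True, False, True]),
        )
        out = preprocess_pupil_trace(tr)
        assert out.diameter[1] == pytest.approx(11.0)

    def test_edges_held_at_nearest_valid(self):
        tr = PupilTrace(
            fs=30.0,
            diameter=np.array([np.nan, 8.0, 9.0, np.nan]),
            valid=np.array([False, True, True, False]),
        )
        out = preprocess_pupil_trace(tr)
        assert out.diameter[0] == 8.0 and out.diameter[-1] == 9.0

    def test_majority_invalid_rejected(self):
        tr = PupilTrace(
            fs=30.0,
            diameter=np.arange(10.0),
            valid=np.array([True] * 4 + [False] * 6),
        )
        with pytest.raises(ValueError, match="rejected"):
            preprocess_pupil_trace(tr)
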