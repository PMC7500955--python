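"""Wall-peak detection, roundness and break detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centromorph import ImagingSpec, generate_top_view
from centromorph.errors import InsufficientPeaksError, NoSignalError
from centromorph.radial_mapping import find_center
from centromorph.shape_integrity import (
    WallPeaks,
    assess_wall_integrity,
    compute_roundness,
    detect_wall_peaks,
    tilt_proxy,
)
from conftest import top_spec


def ellipse_points(n=9, a=13.0, b=13.0, phase=0.0, center=(0.0, 0.0)):
    t = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


class TestDetectWallPeaks:
    def test_intact_ring_has_nine_equally_spaced_peaks(self, noise_free):
        img, _ = generate_top_view(top_spec(orientation_deg=7.0), noise_free)
        peaks = detect_wall_peaks(img, find_center(img))
        assert peaks.n_detected == 9
        spacing = np.diff(np.sort(peaks.thetas_deg))
        assert np.allclose(spacing, 40.0, atol=2.0)

    def test_break_removes_peaks_and_opens_gap(self, noise_free):
        img, _ = generate_top_view(
            top_spec(break_arc_deg=80.0, break_center_deg=100.0), noise_free
        )
        peaks = detect_wall_peaks(img, find_center(img))
        assert peaks.n_detected <= 7
        gaps = np.diff(np.concatenate([np.sort(peaks.thetas_deg),
                                       [peaks.thetas_deg.min() + 360.0]]))
        assert gaps.max() >= 80.0

    def test_peak_set_rotates_with_image(self, noise_free):
        img0, _ = generate_top_view(top_spec(orientation_deg=0.0), noise_free)
        img1, _ = generate_top_view(top_spec(orientation_deg=25.0), noise_free)
        p0 = np.sort(detect_wall_peaks(img0, find_center(img0)).thetas_deg)
        p1 = np.sort(detect_wall_peaks(img1, find_center(img1)).thetas_deg)
        shifted = np.sort((p0 + 25.0) % 360.0)
        assert np.allclose(shifted, p1, atol=1.5)


class TestRoundness:
    def test_circle_is_perfectly_round(self):
        peaks = WallPeaks.from_points(ellipse_points())
        res = compute_roundness(peaks)
        assert res.roundness == pytest.approx(1.0, abs=1e-3)

    def test_half_axis_ratio_ellipse(self):
        peaks = WallPeaks.from_points(ellipse_points(a=13.0, b=6.5))
        res = compute_roundness(peaks)
        assert res.roundness == pytest.approx(0.50, abs=0.02)

    @settings(deadline=None, max_examples=30)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        scale=st.floats(0.5, 3.0),
        tx=st.floats(-20.0, 20.0),
        ty=st.floats(-20.0, 20.0),
    )
    def test_similarity_invariance(self, angle, scale, tx, ty):
        """Rotation, translation, uniform scaling leave roundness fixed."""
        pts = ellipse_points(a=13.0, b=10.0, phase=0.3)
        base = compute_roundness(WallPeaks.from_points(pts)).roundness
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = scale * pts @ R.T + np.array([tx, ty])
        res = compute_roundness(WallPeaks.from_points(moved)).roundness
        assert res == pytest.approx(base, abs=1e-6)

    def test_generator_ellipse_recovery(self, noise_free, calib):
        img, _ = generate_top_view(
            top_spec(ellipse_ratio=0.8, orientation_deg=40.0), noise_free
        )
        peaks = detect_wall_peaks(img, find_center(img))
        res = compute_roundness(peaks, calib)
        assert res.roundness == pytest.approx(0.80, abs=0.03)

    def test_monotone_in_ellipse_ratio(self, calib):
        values = []
        for ratio in (1.0, 0.9, 0.8, 0.7):
            imaging = ImagingSpec(calib=calib, seed=31)
            img, _ = generate_top_view(
                top_spec(ellipse_ratio=ratio, orientation_deg=12.0), imaging
            )
            peaks = detect_wall_peaks(img, find_center(img))
            values.append(compute_roundness(peaks).roundness)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_too_few_peaks_rejected(self):
        with pytest.raises(InsufficientPeaksError):
            compute_roundness(WallPeaks.from_points(ellipse_points(n=4)))

    def test_tilt_proxy_admission(self, noise_free):
        img, _ = generate_top_view(top_spec(), noise_free)
        peaks = detect_wall_peaks(img, find_center(img))
        assert tilt_proxy(peaks) < 0.15


class TestWallIntegrity:
    def test_intact_noise_free_ring(self, noise_free):
        img, _ = generate_top_view(top_spec(), noise_free)
        res = assess_wall_integrity(img, find_center(img))
        assert not res.broken
        # inter-triplet voids of an intact nine-fold ring stay far below
        # the 30 deg break threshold at the default acquisition blur
        assert res.largest_gap_deg < 15.0

    def test_sixty_degree_break_flagged(self, calib):
        imaging = ImagingSpec(calib=calib, seed=17)
        img, _ = generate_top_view(
            top_spec(break_arc_deg=60.0, break_center_deg=211.0), imaging
        )
        res = assess_wall_integrity(img, find_center(img))
        assert res.broken
        # a 60 deg break deletes 1-2 wall elements -> void between the
        # flanking triplets minus the PSF flank penetration
        assert 30.0 <= res.largest_gap_deg <= 100.0

    def test_gap_location_inside_break(self, noise_free):
        img, _ = generate_top_view(
            top_spec(break_arc_deg=80.0, break_center_deg=150.0, orientation_deg=0.0),
            noise_free,
        )
        res = assess_wall_integrity(img, find_center(img))
        assert res.broken
        assert abs((res.gap_location_deg - 150.0 + 180) % 360 - 180) < 25.0

    def test_empty_image_raises(self):
        with pytest.raises(NoSignalError):
            assess_wall_integrity(np.zeros((2, 40, 40)), (19.5, 19.5))

    def test_detector_roc_on_balanced_set(self, calib):
        """Sensitivity >= 0.9 / specificity >= 0.95 at default settings."""
        hits = fas = 0
        n = 20
        for i in range(n):
            imaging = ImagingSpec(calib=calib, seed=100 + i)
            broken, _ = generate_top_view(
                top_spec(break_arc_deg=60.0, break_center_deg=i * 18.0), imaging
            )
            intact, _ = generate_top_view(top_spec(orientation_deg=i * 11.0), imaging)
            if assess_wall_integrity(broken, find_center(broken)).broken:
                hits += 1
            if assess_wall_integrity(intact, find_center(intact)).broken:
                fas += 1
        assert hits / n >= 0.9
        assert 1 - fas / n >= 0.95
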