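"""Landmark localization: contours, extrema, corners, TS/DS selection."""

import numpy as np
import pytest

from sellamorph.landmarks import (
    CornerParams,
    LandmarkError,
    contour_points,
    detect_corners,
    find_extrema,
    locate_landmarks,
    select_ts_ds,
    smooth_for_corners,
)
from sellamorph.types import Point


def square_mask(shape=(60, 60), y=20, x=20, side=10):
    m = np.zeros(shape, dtype=bool)
    m[y : y + side, x : x + side] = True
    return m


class TestContourPoints:
    def test_filled_square_perimeter_count(self):
        pts = contour_points(square_mask())
        assert len(pts) == 36  # 4 * (10 - 1)
        assert len(set(pts)) == 36

    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 6] = True
        assert contour_points(m) == [Point(6, 4)]

    def test_full_frame_is_border_ring(self):
        m = np.ones((8, 8), dtype=bool)
        pts = set(contour_points(m))
        expected = {
            Point(x, y)
            for y in range(8)
            for x in range(8)
            if y in (0, 7) or x in (0, 7)
        }
        assert pts == expected

    def test_every_point_touches_background(self):
        import sellamorph as sm

        samp = sm.make_sample(21, canvas_size=128)
        padded = np.pad(samp.mask, 1)
        for p in contour_points(samp.mask):
            assert samp.mask[p.y, p.x]
            neigh = padded[p.y : p.y + 3, p.x : p.x + 3]
            assert not neigh.all()

    def test_empty_mask_raises(self):
        with pytest.raises(LandmarkError):
            contour_points(np.zeros((5, 5), dtype=bool))


class TestFindExtrema:
    def test_rectangle_extrema(self):
        m = np.zeros((250, 250), dtype=bool)
        m[100:181, 50:151] = True
        adp, bpf = find_extrema(contour_points(m))
        assert adp.x == 50
        assert bpf.y == 180

    def test_leftmost_tie_smaller_y_wins(self):
        contour = [Point(5, 9), Point(5, 3), Point(8, 1)]
        adp, _ = find_extrema(contour)
        assert adp == Point(5, 3)

    def test_bottommost_tie_smaller_x_wins(self):
        contour = [Point(9, 7), Point(2, 7), Point(4, 1)]
        _, bpf = find_extrema(contour)
        assert bpf == Point(2, 7)

    def test_synthetic_extrema_exact(self, samples400):
        for samp in samples400:
            adp, bpf = find_extrema(contour_points(samp.mask))
            assert adp == samp.landmarks.adp
            assert bpf == samp.landmarks.bpf


class TestSmoothForCorners:
    def test_constant_mask_stays_constant(self):
        out = smooth_for_corners(np.ones((20, 20), dtype=bool))
        assert np.allclose(out, 255.0)

    def test_step_edge_monotone_ramp(self):
        m = np.zeros((20, 20), dtype=bool)
        m[:, 10:] = True
        row = smooth_for_corners(m)[10]
        assert (np.diff(row) >= -1e-6).all()
        assert row[0] < 1 and row[-1] > 254

    def test_gaussian_semigroup(self):
        rng = np.random.default_rng(2)
        m = rng.random((40, 40)) > 0.5
        once = smooth_for_corners(smooth_for_corners(m) > 127, sigma=1.0)
        # semigroup holds only approximately for truncated kernels; check
        # the smoothing operator against scipy's with matching truncation
        from scipy import ndimage

        direct = ndimage.gaussian_filter(
            np.where(m, 255.0, 0.0).astype(np.float32), sigma=1.0, truncate=2.0
        )
        np.testing.assert_allclose(smooth_for_corners(m, sigma=1.0), direct, atol=1e-4)


class TestDetectCorners:
    def test_rectangle_corners_found(self):
        m = np.zeros((200, 200), dtype=bool)
        m[60:141, 40:161] = True
        corners = detect_corners(
            smooth_for_corners(m), CornerParams(max_corners=4, min_distance=40)
        )
        assert len(corners) == 4
        vertices = [(40, 60), (160, 60), (40, 140), (160, 140)]
        for c in corners:
            assert min(np.hypot(c.x - vx, c.y - vy) for vx, vy in vertices) <= 3

    def test_agrees_with_skimage_on_rectangle(self):
        from skimage.feature import corner_peaks, corner_shi_tomasi

        m = np.zeros((200, 200), dtype=bool)
        m[60:141, 40:161] = True
        smoothed = smooth_for_corners(m)
        ours = detect_corners(smoothed, CornerParams(max_corners=4, min_distance=20))
        ref = corner_peaks(corner_shi_tomasi(smoothed), min_distance=20,
                           threshold_rel=0.01)
        assert len(ref) == 4
        for c in ours:
            assert min(np.hypot(c.x - x, c.y - y) for y, x in ref) <= 3

    def test_constant_image_raises(self):
        with pytest.raises(LandmarkError, match="no corners"):
            detect_corners(np.full((50, 50), 7.0))

    def test_huge_min_distance_returns_single_corner(self):
        m = np.zeros((100, 100), dtype=bool)
        m[30:71, 20:81] = True
        corners = detect_corners(
            smooth_for_corners(m), CornerParams(max_corners=4, min_distance=1000)
        )
        assert len(corners) == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_corners": 1},
            {"quality_level": 0.0},
            {"quality_level": 1.5},
            {"min_distance": -1},
            {"block_size": 4},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CornerParams(**kwargs)


class TestSelectTsDs:
    def test_screen_by_ordinate_then_abscissa(self):
        corners = [Point(60, 40), Point(160, 35), Point(110, 190)]
        ts, ds = select_ts_ds(corners)
        assert ts == Point(160, 35)
        assert ds == Point(60, 40)

    def test_equal_ordinates_larger_abscissa_is_ts(self):
        ts, ds = select_ts_ds([Point(30, 12), Point(90, 12)])
        assert ts == Point(90, 12)
        assert ds == Point(30, 12)

    def test_single_corner_raises(self):
        with pytest.raises(LandmarkError):
            select_ts_ds([Point(5, 5)])


class TestLocateLandmarks:
    def test_rectangle_geometry(self):
        m = np.zeros((300, 300), dtype=bool)
        m[100:181, 80:231] = True
        lm = locate_landmarks(m)
        assert np.hypot(lm.ts.x - 230, lm.ts.y - 100) <= 3
        assert np.hypot(lm.ds.x - 80, lm.ds.y - 100) <= 3
        assert lm.adp.x == 80
        assert lm.bpf.y == 180

    def test_synthetic_within_3px(self, sample400):
        lm = locate_landmarks(sample400.mask)
        gt = sample400.landmarks
        for name in ("ts", "ds", "adp", "bpf"):
            p, q = getattr(lm, name), getattr(gt, name)
            assert np.hypot(p.x - q.x, p.y - q.y) <= 3, name

    def test_translation_equivariance(self, sample400):
        dy, dx = 11, 7
        shifted = np.roll(sample400.mask, (dy, dx), axis=(0, 1))
        lm0 = locate_landmarks(sample400.mask)
        lm1 = locate_landmarks(shifted)
        # contour extrema shift exactly; corner points within 1 px
        assert lm1.adp == Point(lm0.adp.x + dx, lm0.adp.y + dy)
        assert lm1.bpf == Point(lm0.bpf.x + dx, lm0.bpf.y + dy)
        for name in ("ts", "ds"):
            p, q = getattr(lm1, name), getattr(lm0, name)
            assert abs(p.x - (q.x + dx)) <= 1 and abs(p.y - (q.y + dy)) <= 1

    def test_deterministic(self, sample400):
        assert locate_landmarks(sample400.mask) == locate_landmarks(sample400.mask)
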