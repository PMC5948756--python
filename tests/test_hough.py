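import math

import numpy as np
import pytest

from csfcount import DetectionParams
from csfcount.errors import ValidationError
from csfcount.hough import (
    Detection,
    candidate_radii,
    edge_map,
    find_circles,
    hough_accumulate,
    match_detections,
)
from csfcount.image import ImageFrame, quantize

from conftest import make_disk_frame

PX = 0.476


def _frame(arr: np.ndarray) -> ImageFrame:
    return ImageFrame(quantize(arr, 16), 16, PX, "bright_field")


class TestEdgeMap:
    def test_uniform_image_has_no_edges(self):
        e = edge_map(_frame(np.full((64, 64), 1000.0)))
        assert not e.mask.any()

    def test_tiny_image_rejected(self):
        with pytest.raises(ValidationError):
            edge_map(np.zeros((16, 16)))

    def test_vertical_step_gradient_is_horizontal(self):
        arr = np.full((64, 64), 1000.0)
        arr[:, 32:] = 30000.0
        e = edge_map(_frame(arr))
        ys, xs = np.nonzero(e.mask)
        interior = (ys > 2) & (ys < 61)
        ang = np.degrees(np.arctan2(e.gy[ys, xs][interior], e.gx[ys, xs][interior]))
        ang = np.abs((ang + 90) % 180 - 90)  # fold to [0, 90] from horizontal
        assert ang.max() < 5.0

    def test_disk_boundary_forms_a_ring(self):
        """At least 80% of edge-mask pixels sit within 1.5 px of the circle."""
        n, cx, cy, r = 96, 48.3, 47.6, 13.0
        yy, xx = np.mgrid[0:n, 0:n]
        rho = np.hypot(xx - cx, yy - cy)
        arr = 30000.0 - 14000.0 / (1.0 + np.exp((rho - r) / 0.6))
        e = edge_map(_frame(arr), edge_percentile=0.9)
        ys, xs = np.nonzero(e.mask)
        dist = np.abs(np.hypot(xs - cx, ys - cy) - r)
        assert ys.size > 0
        assert (dist <= 1.5).mean() >= 0.8

    def test_explicit_percentile_mode(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(1000, 50, (64, 64))
        e = edge_map(arr, edge_percentile=0.95)
        assert 0.03 < e.mask.mean() < 0.07


class TestHoughAccumulate:
    def _disk_edges(self, n, cx, cy, r):
        yy, xx = np.mgrid[0:n, 0:n]
        rho = np.hypot(xx - cx, yy - cy)
        arr = 30000.0 - 15000.0 / (1.0 + np.exp((rho - r) / 0.6))
        return edge_map(arr)

    def test_perfect_circle_peaks_at_center(self):
        n, cx, cy, r_px = 96, 48, 48, 12.0
        e = self._disk_edges(n, cx, cy, r_px)
        radii_um = np.array([10.0, 11.0, 12.0, 13.0, 14.0]) * PX
        acc = hough_accumulate(e, radii_um, PX)
        iy, ix, k = np.unravel_index(np.argmax(acc), acc.shape)
        assert math.hypot(iy - cy, ix - cx) <= 1.0
        assert radii_um[k] / PX == pytest.approx(r_px, abs=1.0)
        assert acc[iy, ix, k] >= 0.8

    def test_two_disjoint_circles_two_maxima(self):
        n = 128
        yy, xx = np.mgrid[0:n, 0:n]
        arr = np.full((n, n), 30000.0)
        for cx, cy in ((40, 44), (92, 88)):
            rho = np.hypot(xx - cx, yy - cy)
            arr -= 15000.0 * np.exp(-((rho - 12.0) ** 2) / 2.0)
        e = edge_map(arr)
        acc = hough_accumulate(e, np.array([12.0 * PX]), PX)[:, :, 0]
        m1 = np.unravel_index(np.argmax(acc), acc.shape)
        masked = acc.copy()
        masked[m1[0] - 5 : m1[0] + 6, m1[1] - 5 : m1[1] + 6] = 0
        m2 = np.unravel_index(np.argmax(masked), masked.shape)
        found = sorted([(m1[1], m1[0]), (m2[1], m2[0])])
        for (fx, fy), (tx, ty) in zip(found, [(40, 44), (92, 88)]):
            assert math.hypot(fx - tx, fy - ty) <= 1.5

    def test_empty_mask_gives_zero_accumulator(self):
        e = edge_map(np.full((64, 64), 500.0))
        acc = hough_accumulate(e, np.array([5.0]), PX)
        assert not acc.any()

    def test_radii_must_increase(self):
        e = edge_map(np.full((64, 64), 500.0))
        with pytest.raises(ValidationError):
            hough_accumulate(e, np.array([5.0, 4.0]), PX)


class TestCandidateRadii:
    def test_span_covers_diameter_band(self):
        r = candidate_radii(DetectionParams())
        assert r[0] == pytest.approx(4.3)
        assert r[-1] == pytest.approx(7.1)
        assert np.all(np.diff(r) > 0)


class TestFindCircles:
    def test_blank_noise_frame_has_no_detections(self):
        rng = np.random.default_rng(3)
        frame = _frame(rng.normal(30000, 250, (256, 256)))
        assert find_circles(frame, DetectionParams()) == []

    def test_planted_disks_recovered(self):
        frame, placed = make_disk_frame(seed=42, n=128)
        dets = find_circles(frame, DetectionParams())
        assert len(dets) == len(placed)
        for cx, cy, r in placed:
            best = min(dets, key=lambda d: math.hypot(d.cx / PX - cx, d.cy / PX - cy))
            assert math.hypot(best.cx / PX - cx, best.cy / PX - cy) <= 2.0
            assert abs(best.radius / PX - r) <= 1.2
            assert best.score >= 0.9

    def test_threshold_monotonicity(self):
        """Lowering the sensitivity threshold never loses detections."""
        frame, _ = make_disk_frame(seed=7, n=160, n_circles=(3, 3))
        counts = [
            len(find_circles(frame, DetectionParams(sensitivity_threshold=s)))
            for s in (0.95, 0.9, 0.7, 0.5)
        ]
        assert counts == sorted(counts)

    def test_translation_equivariance(self):
        """Shifting the image by whole pixels shifts detections identically."""
        frame, _ = make_disk_frame(seed=12, n=128, n_circles=(1, 1), noise_sd=80)
        k = 9
        rolled = ImageFrame(np.roll(frame.pixels, (k, k), axis=(0, 1)),
                            16, PX, "bright_field")
        d0 = find_circles(frame, DetectionParams())
        d1 = find_circles(rolled, DetectionParams())
        assert len(d0) == len(d1) == 1
        assert d1[0].cx / PX - d0[0].cx / PX == pytest.approx(k, abs=0.3)
        assert d1[0].cy / PX - d0[0].cy / PX == pytest.approx(k, abs=0.3)

    def test_frame_smaller_than_d_max_rejected(self):
        frame = _frame(np.full((24, 200), 1000.0))
        with pytest.raises(ValidationError):
            find_circles(frame, DetectionParams())

    def test_scores_and_radii_respect_contract(self):
        frame, _ = make_disk_frame(seed=21, n=160, n_circles=(2, 3))
        p = DetectionParams()
        for d in find_circles(frame, p):
            assert d.score >= p.sensitivity_threshold
            assert p.d_min <= 2 * d.radius <= p.d_max
            assert d.modality == "bright_field"


class TestMatchDetections:
    @staticmethod
    def _det(x, y):
        return Detection(cx=x, cy=y, radius=5.0, score=1.0, modality="bright_field")

    def test_identical_lists_fully_match_at_zero(self):
        a = [self._det(3, 4), self._det(50, 60)]
        m = match_detections(a, list(a), tol=1.0)
        assert m.n_matched == 2
        assert all(d == 0 for _, _, d in m.pairs)

    def test_distance_beyond_tolerance_rejected(self):
        m = match_detections([self._det(10, 10)], [self._det(10, 18)], tol=5.0)
        assert m.n_matched == 0
        assert m.unmatched_a == (0,) and m.unmatched_b == (0,)

    def test_greedy_prefers_globally_closest(self):
        a = [self._det(0, 0), self._det(20, 0)]
        b = [self._det(1, 0)]
        m = match_detections(a, b, tol=5.0)
        assert m.pairs == ((0, 0, 1.0),)
        assert m.unmatched_a == (1,)

    def test_each_item_used_at_most_once(self):
        a = [self._det(0, 0), self._det(2, 0)]
        b = [self._det(1, 0)]
        m = match_detections(a, b, tol=5.0)
        assert m.n_matched == 1
        assert len(m.unmatched_a) == 1

    def test_accepts_bare_points(self):
        m = match_detections([self._det(5, 5)], [(5.5, 5.0)], tol=1.0)
        assert m.n_matched == 1

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            match_detections([], [], tol=0.0)
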