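import numpy as np
import pytest

from segquant.errors import ParameterError
from segquant.filters import (
    BoundaryTrace,
    boundary_length_filter,
    default_shape_noise_threshold,
    noise_blob_filter,
    rebuild_blobs,
    smooth_boundary,
    smooth_mask,
    trace_boundaries,
)

from conftest import random_blob_mask

DIAMOND_PTS = [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)]


def _oracle_erode(mask):
    """Set-definition erosion: z is kept iff every translate of the element
    lands on foreground (points outside the image count as background)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in DIAMOND_PTS
            )
    return out


def _oracle_dilate(mask):
    """Set-definition dilation: z is set iff the reflected element touches
    the foreground."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = any(
                0 <= r - dr < h and 0 <= c - dc < w and mask[r - dr, c - dc]
                for dr, dc in DIAMOND_PTS
            )
    return out


def _oracle_open(mask, n):
    out = mask.copy()
    for _ in range(n):
        out = _oracle_erode(out)
    for _ in range(n):
        out = _oracle_dilate(out)
    return out


class TestNoiseBlobFilter:
    def test_thin_line_removed(self):
        m = np.zeros((20, 60), bool)
        m[10, 5:55] = True
        assert not noise_blob_filter(m, 3).any()

    def test_square_matches_oracle_and_keeps_interior(self):
        # opening by the iterated diamond chamfers the square's corners but
        # must restore everything else; the oracle fixes the exact answer
        m = np.zeros((30, 30), bool)
        m[4:25, 4:25] = True
        out = noise_blob_filter(m, 3)
        np.testing.assert_array_equal(out, _oracle_open(m, 3))
        assert (m & ~out).sum() == 4 * 6  # 6 px clipped per corner
        np.testing.assert_array_equal(out[7:22, 7:22], m[7:22, 7:22])

    def test_diamond_blob_restored_exactly(self):
        # an l1-ball is a union of translates of the element, so opening
        # reproduces it exactly
        yy, xx = np.mgrid[:30, :30]
        m = np.abs(yy - 15) + np.abs(xx - 15) <= 8
        np.testing.assert_array_equal(noise_blob_filter(m, 3), m)

    def test_mixture_keeps_massive_blobs_only(self):
        m = np.zeros((40, 40), bool)
        m[5:20, 5:20] = True   # massive
        m[30, 2:38] = True     # thread
        m[2:38, 35] = True     # thread
        out = noise_blob_filter(m, 3)
        from scipy import ndimage

        assert ndimage.label(out)[1] == 1
        assert out[10, 10]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((24, 24)) < 0.55
        np.testing.assert_array_equal(noise_blob_filter(m, 2), _oracle_open(m, 2))

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            m = rng.random((32, 32)) < 0.5
            once = noise_blob_filter(m, 3)
            np.testing.assert_array_equal(noise_blob_filter(once, 3), once)
            assert not (once & ~m).any()


class TestTraceBoundaries:
    def test_rectangle_trace_length(self):
        m = np.zeros((10, 12), bool)
        m[2:6, 3:9] = True  # 4 x 6
        traces = trace_boundaries(m)
        assert len(traces) == 1
        assert len(traces[0]) == 2 * (6 - 1) + 2 * (4 - 1)
        assert traces[0].kind == "outer"

    def test_rectangle_with_hole_topology(self):
        m = np.zeros((12, 12), bool)
        m[2:9, 2:10] = True
        m[4:6, 5:7] = False
        kinds = sorted(t.kind for t in trace_boundaries(m))
        assert kinds == ["hole", "outer"]

    def test_empty_mask(self):
        assert trace_boundaries(np.zeros((5, 5), bool)) == []

    def test_closed_and_adjacent(self):
        m = random_blob_mask(np.random.default_rng(3))
        for t in trace_boundaries(m):
            d = np.abs(t.points[0] - t.points[-1]).max()
            assert d <= 1 or len(t) == 1


class TestBoundaryLengthFilter:
    def _trace(self, n, kind="outer", parent=1):
        return BoundaryTrace(points=np.zeros((n, 2), dtype=int), kind=kind, parent=parent)

    def test_keeps_long_traces(self):
        traces = [self._trace(10), self._trace(50), self._trace(200)]
        kept = boundary_length_filter(traces, 30)
        assert sorted(len(t) for t in kept) == [50, 200]

    def test_zero_threshold_keeps_all(self):
        traces = [self._trace(10), self._trace(50)]
        assert len(boundary_length_filter(traces, 0)) == 2

    def test_small_hole_filled_in_rebuild(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        m[6:8, 6:8] = False
        traces = trace_boundaries(m)
        kept = boundary_length_filter(traces, 10)  # hole trace has 4 points
        out = rebuild_blobs(kept, m.shape)
        assert out[6, 6] and out[2, 2]

    def test_removed_outer_removes_blob(self):
        m = np.zeros((20, 20), bool)
        m[2:12, 2:12] = True
        m[16:18, 16:18] = True
        traces = trace_boundaries(m)
        out = rebuild_blobs(boundary_length_filter(traces, 10), m.shape)
        assert out[5, 5] and not out[16:18, 16:18].any()

    def test_default_threshold_fraction_of_mean_length(self):
        traces = [self._trace(40), self._trace(80), self._trace(6, kind="hole")]
        assert default_shape_noise_threshold(traces) == pytest.approx(0.25 * 60)


def _circle_trace(radius=20, size=50):
    yy, xx = np.mgrid[:size, :size]
    m = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    return m, trace_boundaries(m)[0]


class TestSmoothBoundary:
    def test_full_band_identity_up_to_rounding(self):
        _, tr = _circle_trace()
        out = smooth_boundary(tr, (len(tr) - 2) // 2)
        assert np.abs(out.points - tr.points).max() <= 1

    def test_circle_nearly_invariant_at_low_bandwidth(self):
        # a circle's coordinate spectrum is concentrated in Fourier bin 1
        m, tr = _circle_trace()
        out = smooth_boundary(tr, 2)
        assert np.abs(out.points - tr.points).max() <= 1

    def test_square_corners_rounded_with_bounded_deviation(self):
        m = np.zeros((40, 40), bool)
        m[5:35, 5:35] = True  # side 30
        tr = trace_boundaries(m)[0]
        out = smooth_boundary(tr, 2)
        dev = np.abs(out.points.astype(float) - tr.points).max()
        assert 0 < dev <= 30 * 0.15

    def test_centroid_conserved_to_rounding(self):
        for seed in range(5):
            m = random_blob_mask(np.random.default_rng(seed))
            for tr in trace_boundaries(m):
                if len(tr) < 26:
                    continue
                out = smooth_boundary(tr, 10)
                shift = np.abs(
                    out.points.mean(axis=0) - tr.points.mean(axis=0)
                ).max()
                assert shift <= 0.5

    def test_too_short_trace_rejected(self):
        tr = BoundaryTrace(points=np.zeros((8, 2), dtype=int))
        with pytest.raises(ParameterError):
            smooth_boundary(tr, 4)


class TestRebuild:
    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_identity_hole_free(self, seed):
        m = random_blob_mask(np.random.default_rng(seed))
        traces = trace_boundaries(m)
        out = rebuild_blobs([t for t in traces if t.kind == "outer"], m.shape)
        np.testing.assert_array_equal(out, m)

    def test_annulus_from_outer_plus_hole(self):
        m = np.zeros((20, 20), bool)
        m[3:17, 3:17] = True
        m[8:12, 8:12] = False
        out = rebuild_blobs(trace_boundaries(m), m.shape)
        np.testing.assert_array_equal(out, m)

    def test_smooth_mask_keeps_massive_blob(self):
        m = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[:40, :40]
        m |= (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        out = smooth_mask(m, shape_noise_threshold=0, bandwidth=5)
        # smoothing a disk barely changes it
        assert (out & m).sum() / m.sum() > 0.9
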