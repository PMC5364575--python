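import numpy as np
import pytest

from segquant.errors import (
    CalibrationError,
    DegenerateInputError,
    ParameterError,
    ThresholdSelectionError,
)
from segquant.sdd import (
    SlopeDifferenceDistribution,
    ThresholdRequest,
    dft_lowpass,
    ensure_8bit,
    normalized_histogram,
    rescale_to_255,
    select_real_peaks,
    select_threshold,
    slope_difference,
    threshold_image,
)


class TestRescale:
    def test_linear_scaling(self):
        out = rescale_to_255(np.array([[0, 510], [510, 0]]))
        assert set(np.unique(out)) == {0, 255}

    def test_identity_when_max_is_255(self):
        img = np.array([[0, 17, 255]])
        np.testing.assert_array_equal(rescale_to_255(img), img)

    def test_hand_computed_values(self):
        out = rescale_to_255(np.array([10.0, 20.0, 40.0]))
        np.testing.assert_array_equal(out, [64, 128, 255])

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            rescale_to_255(np.zeros((4, 4)))

    def test_ensure_8bit_passthrough_and_rescale(self):
        img = np.array([[50, 120, 220]])
        np.testing.assert_array_equal(ensure_8bit(img), img)
        np.testing.assert_array_equal(ensure_8bit(img * 2.0), [[58, 139, 255]])


class TestNormalizedHistogram:
    def test_two_level_counts(self):
        img = np.concatenate([np.full(60, 50), np.full(40, 200)])
        p = normalized_histogram(img)
        assert p[50] == 1.0
        assert p[200] == pytest.approx(40 / 60)
        assert p.sum() == pytest.approx(1.0 + 40 / 60)

    def test_constant_image(self):
        p = normalized_histogram(np.full((5, 5), 7))
        assert p[7] == 1.0 and p.sum() == 1.0

    def test_uniform_image_all_ones(self):
        p = normalized_histogram(np.arange(256))
        assert np.all(p == 1.0)


class TestDftLowpass:
    def test_full_band_is_identity(self):
        rng = np.random.default_rng(2)
        sig = rng.random(256)
        np.testing.assert_allclose(dft_lowpass(sig, 128), sig, atol=1e-9)

    def test_constant_signal_unchanged(self):
        np.testing.assert_allclose(dft_lowpass(np.full(256, 0.3), 1), 0.3, atol=1e-12)

    def test_single_bin_cosine_removed_or_kept(self):
        x = np.arange(256)
        sig = np.cos(2 * np.pi * 3 * x / 256)
        assert np.max(np.abs(dft_lowpass(sig, 2))) < 1e-9
        np.testing.assert_allclose(dft_lowpass(sig, 3), np.abs(sig), atol=1e-9)

    def test_mean_conserved(self):
        rng = np.random.default_rng(3)
        sig = rng.random(256)
        # k = 0 coefficient survives any bandwidth
        spec = np.fft.fft(sig)
        spec[3:-2] = 0
        np.testing.assert_allclose(np.fft.ifft(spec).real.mean(), sig.mean(), atol=1e-9)

    @pytest.mark.parametrize("w", [0, 129])
    def test_bandwidth_validated(self, w):
        with pytest.raises(ParameterError):
            dft_lowpass(np.zeros(256), w)


class TestSlopeDifference:
    def test_straight_line_gives_zero_sdd(self):
        d = slope_difference(np.linspace(0.0, 1.0, 256), 10)
        np.testing.assert_allclose(d.s, 0.0, atol=1e-12)
        assert d.peaks == [] and d.valleys == []

    def test_triangle_apex_is_peak_and_corners_are_valleys(self):
        # rising then falling histogram: its apex is a class centre, hence
        # an SDD maximum under the outward-window sign convention
        sig = np.concatenate([np.linspace(0, 1, 129), np.linspace(1, 0, 128)[1:]])
        sig += 1e-4  # keep strictly positive
        d = slope_difference(sig, 10)
        apex = max(d.peaks, key=lambda pm: pm[1])
        assert abs(apex[0] - 128) <= 1
        # the triangle's corners sit at the domain edges, so no comparable
        # valley exists anywhere
        assert all(abs(m) < 0.25 * apex[1] for _, m in d.valleys)

    def test_gaussian_bump_peak_at_centre(self):
        rng = np.random.default_rng(4)
        vals = np.clip(np.round(rng.normal(140, 12, 40000)), 0, 255).astype(int)
        p = normalized_histogram(vals)
        d = slope_difference(dft_lowpass(p, 10), 15)
        top = max(d.peaks, key=lambda pm: pm[1])
        assert abs(top[0] - 140) <= 2

    def test_domain_limits(self):
        d = slope_difference(np.linspace(0, 1, 256), 15)
        assert d.positions[0] == 16 and d.positions[-1] == 240

    @pytest.mark.parametrize("n", [2, 61])
    def test_fit_points_validated(self, n):
        with pytest.raises(ParameterError):
            slope_difference(np.zeros(256), n)


def _sdd_with(peaks, valleys):
    return SlopeDifferenceDistribution(
        s=np.zeros(1), positions=np.zeros(1, dtype=int),
        fit_points=10, peaks=peaks, valleys=valleys,
    )


class TestPeakSelection:
    def test_magnitude_ranking(self):
        d = _sdd_with([(30, 9.0), (90, 5.0), (150, 0.01), (200, 0.02)], [])
        assert select_real_peaks(d, 2) == [30, 90]

    def test_single_class_unimodal(self):
        d = _sdd_with([(120, 3.0)], [])
        assert select_real_peaks(d, 1) == [120]

    def test_too_few_peaks_signals_recalibration(self):
        with pytest.raises(CalibrationError):
            select_real_peaks(_sdd_with([(10, 1.0)], []), 2)

    def test_three_class_image_peaks_at_gray_levels(self, three_class):
        img, _ = three_class
        p = normalized_histogram(ensure_8bit(img))
        d = slope_difference(dft_lowpass(p, 10), 15)
        assert select_real_peaks(d, 3) == [50, 120, 220]


class TestSelectThreshold:
    def test_three_class_case1_between_background_and_dark_object(self, three_class):
        img, _ = three_class
        res = threshold_image(img, ThresholdRequest(class_count=3, case_id=1))
        assert 50 < res.threshold < 120

    def test_three_class_case2_between_object_classes(self, three_class):
        img, _ = three_class
        res = threshold_image(img, ThresholdRequest(class_count=3, case_id=2))
        assert 120 < res.threshold < 220

    def test_threshold_in_open_interval_between_peaks(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals = np.concatenate(
                [r.normal(90, 14, 20000), r.normal(155, 14, 20000)]
            )
            img = np.clip(np.round(vals), 0, 255).astype(int)
            res = threshold_image(img, ThresholdRequest())
            lo, hi = res.real_peaks
            assert lo < res.threshold < hi
            assert 0 <= res.threshold <= 255

    def test_no_valley_between_peaks_raises(self):
        d = _sdd_with([(40, 5.0), (200, 4.0)], [(20, -1.0)])
        with pytest.raises(ThresholdSelectionError):
            select_threshold(
                d, [40, 200], ThresholdRequest(), np.eye(1, 256, 40).ravel()
            )

    def test_request_validation(self):
        with pytest.raises(ParameterError):
            ThresholdRequest(class_count=1)
        with pytest.raises(ParameterError):
            ThresholdRequest(class_count=2, case_id=2)
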