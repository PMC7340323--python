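"""Count model, decay correction, ROI statistics, fits and regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rlm import quantification as q
from rlm.errors import InvalidArgumentError, UndefinedRatioError
from rlm.reconstruction import EventImage


class TestExpectedCounts:
    def test_zero_elapsed_time(self):
        assert q.expected_counts(1e4, 0.5, 0.97, 0.0, 110.0) == 0.0

    def test_infinite_time_limit(self):
        d = q.expected_counts(1e4, 0.5, 0.97, 1e9, 110.0)
        assert d == pytest.approx(0.5 * 0.97 * 1e4, rel=1e-12)

    def test_one_half_life(self):
        d = q.expected_counts(1e4, 0.5, 0.97, 110.0, 110.0)
        assert d == pytest.approx(0.5 * 0.97 * 1e4 / 2, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            q.expected_counts(-1, 0.5, 0.97, 10.0, 110.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t1=st.floats(0.1, 500), dt=st.floats(0.1, 500),
           n0=st.floats(1, 1e6), s=st.floats(0.01, 0.6))
    def test_strictly_increasing_in_time_and_load(self, t1, dt, n0, s):
        d1 = q.expected_counts(n0, s, 0.97, t1, 110.0)
        d2 = q.expected_counts(n0, s, 0.97, t1 + dt, 110.0)
        assert d2 > d1
        assert q.expected_counts(n0 * 2, s, 0.97, t1, 110.0) > d1
        assert q.expected_counts(n0, s * 1.5, 0.97, t1, 110.0) > d1


class TestDecayCorrection:
    def test_paper_value(self):
        assert q.decay_correction_factor(21.0, 110.0) == pytest.approx(1.14, abs=0.005)

    def test_zero_delay(self):
        assert q.decay_correction_factor(0.0, 110.0) == 1.0

    def test_one_half_life(self):
        assert q.decay_correction_factor(110.0, 110.0) == pytest.approx(2.0, rel=1e-12)


class TestSensitivityRatio:
    def test_double_counts_no_delay(self):
        est = q.sensitivity_ratio(200.0, 100.0, 0.0, 110.0)
        assert est.ratio == pytest.approx(2.0)
        assert est.correction_factor == 1.0

    def test_equal_counts_reduce_to_decay_correction(self):
        est = q.sensitivity_ratio(37.0, 37.0, 21.0, 110.0)
        assert est.ratio == pytest.approx(1.14, abs=0.005)

    def test_ci_covers_true_poisson_ratio(self, rng):
        x = rng.poisson(2000)
        y = rng.poisson(1000)
        est = q.sensitivity_ratio(x, y, 0.0, 110.0)
        assert est.ci_low < 2.0 < est.ci_high

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            q.sensitivity_ratio(10.0, 0.0, 0.0, 110.0)

    def test_composition_identity(self):
        # internal consistency of the sign convention
        f, a = 1.7, 500.0
        est = q.sensitivity_ratio(a * f, a, 21.0, 110.0)
        assert est.ratio * np.exp(-np.log(2) * 21.0 / 110.0) == pytest.approx(f, rel=1e-12)


class TestRoiCounts:
    def test_zero_image(self):
        img = EventImage(np.zeros((20, 20), dtype=int), 10.0)
        meas = q.roi_counts(img, [(0.0, 0.0)], diameter_um=90.0)
        assert meas[0].raw_count == 0

    def test_single_pixel_count(self):
        counts = np.zeros((21, 21), dtype=int)
        counts[10, 10] = 7
        img = EventImage(counts, 10.0)
        meas = q.roi_counts(img, [(0.0, 0.0)], diameter_um=50.0)
        assert meas[0].raw_count == 7 and meas[0].background_corrected_count == 7

    def test_matches_pixel_loop_oracle(self, rng):
        pitch = 5.0
        counts = rng.integers(0, 4, (30, 30))
        img = EventImage(counts, pitch)
        centers = [(0.0, 0.0), (20.0, -15.0), (-30.0, 25.0)]
        meas = q.roi_counts(img, centers, diameter_um=40.0)
        for c, m in zip(centers, meas):
            total = 0
            for i in range(30):
                for j in range(30):
                    x = (j - 14.5) * pitch
                    y = (i - 14.5) * pitch
                    if (x - c[0]) ** 2 + (y - c[1]) ** 2 <= 20.0**2:
                        total += counts[i, j]
            assert m.raw_count == total

    def test_background_correction_subtracts_mean(self):
        counts = np.zeros((40, 40), dtype=int)
        counts[20, 20] = 50
        counts[5, 5] = 4
        counts[5, 34] = 6
        img = EventImage(counts, 10.0)
        meas = q.roi_counts(img, [(5.0, 5.0)], diameter_um=60.0,
                            background_rois=[(-145.0, -145.0), (145.0, -145.0)])
        cell = [m for m in meas if m.label == "cell"][0]
        assert cell.raw_count == 50
        assert cell.background_corrected_count == pytest.approx(50 - (4 + 6) / 2)

    def test_out_of_bounds_rejected(self):
        img = EventImage(np.zeros((10, 10), dtype=int), 10.0)
        with pytest.raises(InvalidArgumentError):
            q.roi_counts(img, [(45.0, 45.0)], diameter_um=90.0)


class TestGaussianFit:
    @staticmethod
    def _gaussian_image(shape, cx, cy, sigma, amp, pitch=1.0, offset=0.0):
        h, w = shape
        x = (np.arange(w) - (w - 1) / 2) * pitch
        y = (np.arange(h) - (h - 1) / 2) * pitch
        xx, yy = np.meshgrid(x, y)
        return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)) + offset

    def test_noiseless_closed_form(self):
        img = EventImage(self._gaussian_image((64, 64), 0, 0, 10.0, 100.0), 1.0)
        fit = q.fit_gaussian2d(img)
        assert fit.fwhm_um == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 10.0, abs=0.1)
        assert fit.fwhm_um == pytest.approx(23.55, abs=0.1)

    def test_translation_equivariance(self):
        base = self._gaussian_image((64, 64), 0, 0, 6.0, 80.0)
        f0 = q.fit_gaussian2d(EventImage(base, 1.0))
        shifted = np.roll(np.roll(base, 5, axis=0), -3, axis=1)
        f1 = q.fit_gaussian2d(EventImage(shifted, 1.0))
        assert f1.center_um[0] - f0.center_um[0] == pytest.approx(-3.0, abs=0.05)
        assert f1.center_um[1] - f0.center_um[1] == pytest.approx(5.0, abs=0.05)
        assert f1.sigma_um == pytest.approx(f0.sigma_um, rel=1e-3)

    def test_poisson_recovery_within_five_percent(self, rng):
        sigma_true = 4.0
        errs = []
        for _ in range(100):
            lam = self._gaussian_image((48, 48), rng.uniform(-2, 2),
                                       rng.uniform(-2, 2), sigma_true, 30.0)
            img = EventImage(rng.poisson(lam), 1.0)
            fit = q.fit_gaussian2d(img)
            errs.append(abs(fit.sigma_um - sigma_true) / sigma_true)
        assert np.median(errs) < 0.05

    def test_requires_minimum_counts(self):
        with pytest.raises(InvalidArgumentError):
            q.fit_gaussian2d(EventImage(np.ones((8, 8), dtype=int) * 0, 1.0))


class TestLineProfile:
    def test_uniform_image_normalized_is_one(self):
        img = EventImage(np.full((32, 32), 5, dtype=int), 2.0)
        prof = q.line_profile(img, (-20.0, 0.0), (20.0, 0.0), width_um=10.0,
                              normalize=True)
        np.testing.assert_allclose(prof, 1.0, rtol=1e-6)

    def test_two_blobs_give_two_peaks(self):
        counts = np.zeros((41, 41))
        x = np.arange(41) - 20.0
        xx, yy = np.meshgrid(x, x)
        counts += 100 * np.exp(-((xx + 10) ** 2 + yy**2) / (2 * 2.0**2))
        counts += 100 * np.exp(-((xx - 10) ** 2 + yy**2) / (2 * 2.0**2))
        img = EventImage(np.rint(counts).astype(int), 1.0)
        prof = q.line_profile(img, (-18.0, 0.0), (18.0, 0.0), width_um=6.0)
        mid = len(prof) // 2
        assert prof[mid] < prof[:mid].max()
        assert prof[mid] < prof[mid:].max()

    def test_matches_rotated_rectangle_oracle(self):
        """Band-integrated profile totals agree with brute-force pixel
        membership on a smooth image to 2%."""
        h = w = 48
        x = np.arange(w) - (w - 1) / 2
        xx, yy = np.meshgrid(x, x)
        smooth = 50 + 30 * np.exp(-(xx**2 + yy**2) / (2 * 9.0**2))
        img = EventImage(np.rint(smooth).astype(int), 1.0)
        p0, p1, width = (-15.0, -8.0), (14.0, 11.0), 8.0
        prof = q.line_profile(img, p0, p1, width_um=width)
        u = np.array(p1) - np.array(p0)
        length = np.linalg.norm(u)
        u = u / length
        v = np.array([-u[1], u[0]])
        total_oracle = 0.0
        for i in range(h):
            for j in range(w):
                rel = np.array([x[j], x[i]]) - np.array(p0)
                t, s = rel @ u, rel @ v
                if 0 <= t <= length and abs(s) <= width / 2:
                    total_oracle += img.counts[i, j]
        step = length / (len(prof) - 1)
        total_profile = np.trapezoid(prof, dx=step)
        assert total_profile == pytest.approx(total_oracle, rel=0.02)

    def test_degenerate_segment_rejected(self):
        img = EventImage(np.zeros((8, 8), dtype=int), 1.0)
        with pytest.raises(InvalidArgumentError):
            q.line_profile(img, (0.0, 0.0), (0.0, 0.0), 2.0)


class TestEffluxDifference:
    def test_exact_doubling_cancels(self):
        single = EventImage(np.arange(16).reshape(4, 4), 1.0)
        double = EventImage(2 * np.arange(16).reshape(4, 4), 1.0)
        diff = q.efflux_difference_image(double, single, 0.0, 110.0)
        np.testing.assert_allclose(diff, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 10, (6, 6))
        b = rng.integers(0, 10, (6, 6))
        d1 = q.efflux_difference_image(EventImage(a, 1.0), EventImage(b, 1.0), 21, 110)
        d3 = q.efflux_difference_image(EventImage(3 * a, 1.0), EventImage(3 * b, 1.0),
                                       21, 110)
        np.testing.assert_allclose(d3, 3 * d1, rtol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            q.efflux_difference_image(EventImage(np.zeros((4, 4), dtype=int), 1.0),
                                      EventImage(np.zeros((5, 5), dtype=int), 1.0),
                                      21, 110)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = q.linear_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        res = q.linear_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_matches_closed_form_ols(self, rng):
        x = rng.normal(0, 2, 40)
        y = 1.3 * x + rng.normal(0, 0.5, 40)
        res = q.linear_regression(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = sxy**2 / (sxx * np.sum((y - y.mean()) ** 2))
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-9)
        assert res.r_squared == pytest.approx(r2, rel=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvalidArgumentError):
            q.linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
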