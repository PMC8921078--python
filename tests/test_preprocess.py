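"""Calibration, noise estimation, and bilateral denoising."""

import numpy as np
import pytest

from fractalperf import (
    CalibrationError,
    DceSeries,
    InputError,
    MuscleRoi,
    ParameterError,
    PhantomSpec,
    calibrate,
    denoise,
    estimate_noise,
    generate_phantom,
)


def make_series(data, times=None, spacing=(4.0, 1.5, 1.5), **kw):
    data = np.asarray(data, dtype=float)
    if times is None:
        times = np.arange(data.shape[0]) * 3.5
    return DceSeries(data=data, spacing=spacing, times=times, **kw)


def reference_bilateral(img, sigma_color, sigma_spatial, half=4):
    """Direct O(N^2 w^2) bilateral filter as an independent oracle."""
    ny, nx = img.shape
    out = np.zeros_like(img)
    for i in range(ny):
        for j in range(nx):
            y0, y1 = max(0, i - half), min(ny, i + half + 1)
            x0, x1 = max(0, j - half), min(nx, j + half + 1)
            patch = img[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            w = np.exp(-((yy - i) ** 2 + (xx - j) ** 2) / (2 * sigma_spatial**2))
            w *= np.exp(-((patch - img[i, j]) ** 2) / (2 * sigma_color**2))
            out[i, j] = (w * patch).sum() / w.sum()
    return out


@pytest.fixture
def toy_roi():
    mask = np.zeros((1, 4, 4), dtype=bool)
    mask[0, :2, :2] = True
    return mask


class TestEstimateNoise:
    def test_constant_region_zero(self, toy_roi):
        data = np.full((6, 1, 4, 4), 100.0)
        series = make_series(data)
        roi = MuscleRoi(toy_roi, pre_frames=(0, 1), enhanced_frames=(4, 5))
        assert estimate_noise(series, roi) == 0.0

    def test_hand_computed_sample_sd(self, toy_roi):
        """Muscle voxels {98, 100, 102, 100}: sample sd with n-1 denominator."""
        data = np.full((4, 1, 4, 4), 100.0)
        data[0, 0, :2, :2] = [[98, 100], [102, 100]]
        series = make_series(data)
        roi = MuscleRoi(toy_roi, pre_frames=(0,), enhanced_frames=(3,))
        expected = np.std([98, 100, 102, 100], ddof=1)
        assert estimate_noise(series, roi) == pytest.approx(expected)

    def test_monte_carlo_recovers_generator_sd(self):
        """>= 200 muscle voxels with injected sd-5 noise: estimate in [4, 6]."""
        ph = generate_phantom(PhantomSpec(seed=3, noise_sd=5.0))
        sigma = estimate_noise(ph.series, ph.muscle_roi())
        assert 4.0 <= sigma <= 6.0

    def test_unbiased_under_gaussian_noise(self):
        rng = np.random.default_rng(0)
        mask = np.ones((1, 20, 20), dtype=bool)
        data = 100.0 + rng.normal(0, 3.0, (5, 1, 20, 20))
        series = make_series(data)
        roi = MuscleRoi(mask, pre_frames=(0, 1, 2), enhanced_frames=(4,))
        assert estimate_noise(series, roi) == pytest.approx(3.0, rel=0.05)

    def test_roi_validation(self, toy_roi):
        with pytest.raises(InputError):
            MuscleRoi(np.zeros((1, 4, 4), dtype=bool), (0,), (3,))
        with pytest.raises(InputError):
            MuscleRoi(toy_roi, (0, 1), (1, 2))
        with pytest.raises(InputError):
            MuscleRoi(toy_roi, (), (1,))


class TestCalibrate:
    def _series_and_roi(self):
        data = np.full((4, 1, 4, 4), 150.0)
        data[:2, 0, :2, :2] = 100.0  # muscle pre
        data[2:, 0, :2, :2] = 200.0  # muscle enhanced
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, :2, :2] = True
        return make_series(data), MuscleRoi(mask, (0, 1), (2, 3))

    def test_two_point_anchor_mapping(self):
        """Muscle pre 100 -> 0, enhanced 200 -> 100; value 150 -> 50."""
        series, roi = self._series_and_roi()
        cal = calibrate(series, roi)
        assert cal.calibrated
        assert cal.data[0, 0, 3, 3] == pytest.approx(50.0)
        assert cal.data[list(roi.pre_frames)][:, roi.mask].mean() == pytest.approx(0.0)
        assert cal.data[list(roi.enhanced_frames)][:, roi.mask].mean() == pytest.approx(100.0)

    def test_sigma_rescaled_by_gain(self):
        series, roi = self._series_and_roi()
        series = make_series(series.data, sigma=4.0)
        cal = calibrate(series, roi)
        assert cal.sigma == pytest.approx(4.0)  # gain = 100/100 = 1 here
        tripled = make_series(series.data * 3.0, sigma=12.0)
        cal3 = calibrate(tripled, roi)
        assert cal3.sigma == pytest.approx(4.0)  # gain shrinks 3x

    def test_recalibration_rejected(self):
        series, roi = self._series_and_roi()
        cal = calibrate(series, roi)
        with pytest.raises(CalibrationError):
            calibrate(cal, roi)

    def test_degenerate_enhancement_rejected(self):
        data = np.full((4, 1, 4, 4), 100.0)  # muscle never enhances
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, :2, :2] = True
        with pytest.raises(CalibrationError):
            calibrate(make_series(data), MuscleRoi(mask, (0, 1), (2, 3)))

    def test_affine_invariance_of_calibrated_data(self):
        """Scaling raw data by 3 and shifting by 50 yields identical
        calibrated series, hence identical FD downstream."""
        series, roi = self._series_and_roi()
        cal_a = calibrate(series, roi)
        cal_b = calibrate(make_series(series.data * 3.0 + 50.0), roi)
        np.testing.assert_allclose(cal_a.data, cal_b.data, atol=1e-10)

    def test_series_validation(self):
        with pytest.raises(InputError):
            make_series(np.zeros((3, 1, 4, 4)), times=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(InputError):
            make_series(np.zeros((3, 4, 4)))


class TestDenoise:
    def test_zero_sigma_identity(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 5, (16, 16))
        np.testing.assert_array_equal(denoise(img, sigma=0.0), img)

    def test_variance_reduction_on_noise(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0, 5, (64, 64))
        out = denoise(img, sigma=5.0)
        assert out.var() < img.var()

    def test_negative_parameters_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(ParameterError):
            denoise(img, sigma=-1.0)
        with pytest.raises(ParameterError):
            denoise(img, sigma=1.0, spatial_scale_mm=-2.0)

    def test_step_edge_preserved_against_reference(self):
        """A 20-sigma step: edge position (max-gradient column) unchanged and
        output close to a directly implemented bilateral oracle."""
        rng = np.random.default_rng(3)
        sigma = 1.0
        img = np.zeros((32, 32))
        img[:, 16:] = 20.0 * sigma
        img += rng.normal(0, sigma, img.shape)
        out = denoise(img, sigma=sigma, spatial_scale_mm=1.5, pixel_spacing_mm=1.5)
        grad_in = np.abs(np.diff(img.mean(axis=0)))
        grad_out = np.abs(np.diff(out.mean(axis=0)))
        assert np.argmax(grad_out) == np.argmax(grad_in)
        ref = reference_bilateral(img - img.min(), sigma_color=2.0 * sigma,
                                  sigma_spatial=1.0) + img.min()
        # same edge geometry as the oracle
        assert np.argmax(np.abs(np.diff(ref.mean(axis=0)))) == np.argmax(grad_out)
        # smoothing strength comparable on the flat plateaus
        assert out[:, :12].std() < 0.8 * img[:, :12].std()
        assert ref[:, :12].std() < 0.8 * img[:, :12].std()
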