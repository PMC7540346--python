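import numpy as np
import pytest

from lpfsc import (
    MetricsConfig,
    MetricsReport,
    PAImage,
    ROISpec,
    cnr,
    evaluate_image,
    fwhm,
    psnr,
    ssim_global,
)


class TestPSNR:
    def test_printed_formula_arithmetic(self):
        ref = np.array([1.0, 0.0, 0.0, 0.0])
        est = np.array([0.9, 0.0, 0.0, 0.0])
        # MSE = 0.0025, 20 log10(1/0.0025) = 52.04 dB
        assert psnr(ref, est) == pytest.approx(52.04, abs=0.01)

    def test_identical_inputs_infinite(self):
        assert psnr(np.ones(5), np.ones(5)) == np.inf

    def test_convention_identity(self):
        rng = np.random.default_rng(0)
        ref, est = rng.standard_normal((2, 100))
        mse = np.mean((ref - est) ** 2)
        diff = psnr(ref, est, "as_printed") - psnr(ref, est, "rmse")
        assert diff == pytest.approx(20 * np.log10(np.sqrt(mse) / mse), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros(3), np.zeros(4))


class TestSSIM:
    def test_identity_is_one(self):
        img = np.random.default_rng(1).random((32, 32))
        assert ssim_global(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((2, 16, 16))
        assert ssim_global(a, b) == pytest.approx(ssim_global(b, a), abs=1e-14)

    def test_hand_computed_two_by_two(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 0.0], [0.5, 0.5]])
        c1 = c2 = 1e-4
        mu_a, mu_b = 0.5, 0.25
        var_a, var_b = 0.25, 0.0625
        cov = np.mean((a - mu_a) * (b - mu_b))
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
        )
        got = ssim_global(a, b, MetricsConfig(c1=c1, c2=c2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.random((2, 8, 8))
            assert ssim_global(a, b) <= 1.0 + 1e-12


class TestCNR:
    roi = ROISpec(inside=((10, 20, 10, 20),), outside=(30, 60, 30, 60))

    def _image(self, inside_val, out_mean, out_std, seed=0):
        rng = np.random.default_rng(seed)
        px = rng.normal(out_mean, out_std, (64, 64))
        px[10:20, 10:20] = inside_val
        return px

    def test_direct_arithmetic(self):
        px = self._image(10.0, 2.0, 1e-9)
        # background with exact mean 2 and std 2
        px[30:60, 30:60] = np.tile([0.0, 4.0], (30, 15))
        # |10 - 2| / 2 = 4 -> 20 log10(4) = 12.04 dB
        assert cnr(px, self.roi) == pytest.approx(12.0412, abs=1e-3)

    def test_translation_invariance(self):
        img = self._image(5.0, 1.0, 0.5)
        assert cnr(img + 5.0, self.roi) == pytest.approx(cnr(img, self.roi), abs=1e-9)

    def test_matches_independent_statistics(self):
        img = self._image(3.0, 0.0, 1.0, seed=7)
        s_i = img[10:20, 10:20].mean()
        bg = img[30:60, 30:60]
        expected = 20 * np.log10(abs(s_i - bg.mean()) / bg.std())
        assert cnr(img, self.roi) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_std_rejected(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 1.0
        with pytest.raises(ValueError):
            cnr(img, self.roi)

    def test_roi_validation(self):
        with pytest.raises(ValueError):
            ROISpec(inside=((0, 10, 0, 10),), outside=(5, 15, 5, 15))  # overlap
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            cnr(img, self.roi)  # out of bounds for 8x8


class TestFWHM:
    def test_gaussian_closed_form(self):
        k = np.arange(200)
        sigma = 10.0
        prof = np.exp(-((k - 100.0) ** 2) / (2 * sigma**2))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert fwhm(prof) == pytest.approx(expected, abs=0.1)

    def test_triangle_geometry(self):
        prof = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        assert fwhm(prof) == pytest.approx(10.0, abs=1e-9)

    def test_amplitude_and_spacing_scaling(self):
        k = np.arange(100)
        prof = np.exp(-((k - 50.0) ** 2) / 50.0)
        assert fwhm(5 * prof) == pytest.approx(fwhm(prof))
        assert fwhm(prof, spacing=2.0) == pytest.approx(2 * fwhm(prof))

    def test_peak_at_edge_or_no_crossing_rejected(self):
        with pytest.raises(ValueError):
            fwhm(np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            fwhm(np.full(10, 0.6) + np.eye(10)[5] * 0.1)  # never falls below half


class TestEvaluateImage:
    def _images(self):
        rng = np.random.default_rng(5)
        px = np.abs(rng.normal(0.05, 0.02, (64, 64)))
        ii, jj = np.mgrid[0:64, 0:64]
        px += np.exp(-((ii - 30) ** 2 + (jj - 28) ** 2) / 18.0)
        ref = PAImage(pixels=px, pixel_size=1e-4)
        return ref, PAImage(pixels=px * 1.0, pixel_size=1e-4)

    roi = ROISpec(inside=((22, 40, 20, 38),), outside=(2, 14, 2, 14))

    def test_identity_estimate(self):
        ref, est = self._images()
        rep = evaluate_image(ref, est, self.roi)
        assert rep.ssim == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(rep.cnr_db)

    def test_fields_match_individual_metrics(self):
        ref, est = self._images()
        rep = evaluate_image(ref, est, self.roi)
        assert rep.ssim == pytest.approx(ssim_global(ref.pixels, est.pixels))
        assert rep.cnr_db == pytest.approx(cnr(est, self.roi))
        pi, pj = 30, 28
        assert rep.fwhm_axial_m[0] == pytest.approx(
            fwhm(est.pixels[:, pj], est.pixel_size)
        )
        assert rep.fwhm_lateral_m[0] == pytest.approx(
            fwhm(est.pixels[pi, :], est.pixel_size)
        )

    def test_report_json_roundtrip(self):
        ref, est = self._images()
        rep = evaluate_image(ref, est, self.roi)
        back = MetricsReport.from_json(rep.to_json())
        assert back.ssim == rep.ssim and back.cnr_db == rep.cnr_db
        assert back.fwhm_axial_m == rep.fwhm_axial_m
        assert back.roi.inside == self.roi.inside
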