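"""PSNR/SSIM correctness and ROI segmentation behaviour."""

import numpy as np
import pytest

import orthosr as o
from orthosr.metrics import PSNR_CAP_DB


def brute_force_psnr(ref, test, data_range):
    """Two-line MSE oracle."""
    mse = np.mean((np.asarray(ref, float) - np.asarray(test, float)) ** 2)
    return 10.0 * np.log10(data_range**2 / mse)


def brute_force_ssim(ref, test, data_range, win=11, sigma=1.5, k1=0.01, k2=0.03):
    """Direct per-window evaluation of the SSIM formula.

    Gaussian-weighted means/variances/covariance computed window by
    window, averaged over all positions with full window support.
    """
    r = win // 2
    ax = np.arange(-r, r + 1)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    h, w = ref.shape
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            a = ref[i - r : i + r + 1, j - r : j + r + 1]
            b = test[i - r : i + r + 1, j - r : j + r + 1]
            ua = np.sum(kernel * a)
            ub = np.sum(kernel * b)
            va = np.sum(kernel * a * a) - ua**2
            vb = np.sum(kernel * b * b) - ub**2
            cov = np.sum(kernel * a * b) - ua * ub
            vals.append(
                ((2 * ua * ub + c1) * (2 * cov + c2))
                / ((ua**2 + ub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


class TestPSNR:
    def test_identical_images_hit_cap(self, rng):
        img = rng.random((16, 16))
        assert o.psnr(img, img) == PSNR_CAP_DB

    def test_uniform_offset_closed_form(self):
        """Offset d on range R gives exactly 20·log10(R/d)."""
        ref = np.zeros((32, 32))
        assert o.psnr(ref, ref + 0.1, data_range=1.0) == pytest.approx(20.0)
        assert o.psnr(ref, ref + 40.95, data_range=4095.0) == pytest.approx(40.0)

    def test_agrees_with_mse_oracle(self, rng):
        for _ in range(10):
            a = rng.random((24, 24)) * 4095
            b = rng.random((24, 24)) * 4095
            assert o.psnr(a, b) == pytest.approx(
                brute_force_psnr(a, b, 4095.0), abs=1e-9
            )

    def test_strictly_decreasing_in_mse(self, rng):
        ref = rng.random((16, 16))
        small = o.psnr(ref, ref + 0.01, data_range=1.0)
        large = o.psnr(ref, ref + 0.02, data_range=1.0)
        assert small > large

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            o.psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSSIM:
    def test_identical_images_give_one(self, rng):
        img = rng.random((16, 16))
        assert o.ssim(img, img, data_range=1.0) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((20, 20)), rng.random((20, 20))
        assert o.ssim(a, b, 1.0) == pytest.approx(o.ssim(b, a, 1.0), abs=1e-12)

    @pytest.mark.parametrize("size", [16, 32, 64])
    def test_agrees_with_brute_force_windowed_oracle(self, size, rng):
        a = rng.random((size, size))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        assert o.ssim(a, b, data_range=1.0) == pytest.approx(
            brute_force_ssim(a, b, 1.0), abs=1e-8
        )

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            o.ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_bounded_in_unit_interval_for_positive_images(self, rng):
        a, b = rng.random((20, 20)), rng.random((20, 20))
        assert -1.0 <= o.ssim(a, b, 1.0) <= 1.0


class TestSegmentRois:
    def test_body_box_matches_analytic_extent(self):
        spec = o.PhantomSpec(size=(64, 64, 48), noise_sd=0.0)
        hr = o.make_phantom_hr(spec)
        body, _ = o.segment_rois(hr)
        center = (np.array(spec.size) - 1) / 2.0
        semi = np.array(spec.body_axes) / np.array(spec.spacing)
        for ax in range(3):
            assert abs(body.lo[ax] - np.ceil(center[ax] - semi[ax])) <= 2
            assert abs(body.hi[ax] - np.floor(center[ax] + semi[ax])) <= 2

    def test_lung_box_inside_body_box(self):
        for seed in (0, 1, 2):
            hr = o.make_phantom_hr(o.PhantomSpec(size=(48, 48, 40), seed=seed))
            body, lung = o.segment_rois(hr)
            assert body.contains(lung)

    def test_all_air_volume_is_empty_scan(self):
        geom = o.VolumeGeometry((0, 0, 0), (1, 1, 1), np.eye(3), (16, 16, 16))
        vol = o.CTVolume(np.full((16, 16, 16), -1000.0), geom)
        with pytest.raises(ValueError, match="empty scan"):
            o.segment_rois(vol)


class TestEvaluateCase:
    def test_perfect_reconstruction_scores_one(self, fused_case):
        hr, _ = fused_case
        rec = o.evaluate_case(hr, hr)
        for roi in rec.ssim:
            assert rec.ssim[roi] == pytest.approx(1.0)
            assert rec.psnr[roi] == PSNR_CAP_DB

    def _body_noised(self, hr, rng):
        body_mask = hr.intensities > -999.0
        noisy = hr.intensities + 30.0 * rng.standard_normal(hr.shape) * body_mask
        return hr.copy_with(noisy)

    def test_widening_roi_over_blank_air_raises_psnr(self, fused_case, rng):
        """Zero-error air pixels dilute the MSE and inflate the score."""
        hr, _ = fused_case
        rec = o.evaluate_case(hr, self._body_noised(hr, rng))
        assert rec.psnr["whole-DICOM"] > rec.psnr["body-area"]

    def test_roi_nesting_direction_with_body_confined_error(self, fused_case, rng):
        from scipy import ndimage

        hr, _ = fused_case
        # resolution-loss error model: blur confined to the body
        body_mask = hr.intensities > -999.0
        blurred = ndimage.gaussian_filter(hr.intensities, 1.2)
        test = hr.copy_with(np.where(body_mask, blurred, hr.intensities))
        rec = o.evaluate_case(hr, test)
        assert rec.psnr["whole-DICOM"] >= rec.psnr["body-area"] >= rec.psnr["lung-fields"]
        assert rec.ssim["whole-DICOM"] >= rec.ssim["body-area"] >= rec.ssim["lung-fields"]

    def test_mismatched_grids_rejected(self, fused_case):
        hr, _ = fused_case
        other = o.make_phantom_hr(o.PhantomSpec(size=(24, 24, 20)))
        with pytest.raises(ValueError, match="grid"):
            o.evaluate_case(hr, other)
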