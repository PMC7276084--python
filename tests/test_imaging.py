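"""Chromomere fitting: model recovery, rejection rules, segmentation and
termination."""
import numpy as np
import pytest

from h1contrast import (
    FitParams,
    MicroscopyImage,
    fit_gaussian2d,
    fit_lorentzian2d,
    segment_domains_sted,
    simulate_image_pair,
    size_distribution,
)


def gaussian_image(shape, cx, cy, fwhm_px, amp=100.0, offset=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return offset + amp * np.exp(-4 * np.log(2)
                                 * ((xx - cx) ** 2 + (yy - cy) ** 2)
                                 / fwhm_px ** 2)


def lorentzian_image(shape, cx, cy, fwhm_px, amp=100.0, offset=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return offset + amp / (1 + 4 * ((xx - cx) ** 2 + (yy - cy) ** 2)
                           / fwhm_px ** 2)


class TestGaussianFit:
    def test_noiseless_recovery_210nm(self):
        conf, _, _ = simulate_image_pair([(1280, 1280)], 0.0, pixel_nm=20.0,
                                         photon_scale=None,
                                         image_shape=(128, 128), seed=0)
        fit = fit_gaussian2d(conf, (64, 64), FitParams(roi_half_width=10))
        assert fit.accepted
        assert fit.fwhm_mean == pytest.approx(210.0, rel=0.02)

    def test_anisotropic_spot_mean_fwhm(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 50 * np.exp(-4 * np.log(2) * (((xx - 32) * 20) ** 2 / 180 ** 2
                                            + ((yy - 32) * 20) ** 2 / 240 ** 2))
        m = MicroscopyImage(img, 20.0, "confocal")
        fit = fit_gaussian2d(m, (32, 32), FitParams(roi_half_width=10))
        assert fit.accepted
        assert fit.fwhm_x == pytest.approx(180, rel=0.02)
        assert fit.fwhm_y == pytest.approx(240, rel=0.02)
        assert fit.fwhm_mean == pytest.approx(210, rel=0.02)

    def test_flat_image_rejected(self):
        m = MicroscopyImage(np.full((64, 64), 10.0), 10.0, "confocal")
        fit = fit_gaussian2d(m, (32, 32))
        assert not fit.accepted


class TestLorentzianFit:
    def test_noiseless_recovery_70nm(self):
        img = lorentzian_image((64, 64), 32, 32, 7.0)  # 7 px * 10 nm = 70 nm
        m = MicroscopyImage(img, 10.0, "STED")
        fit = fit_lorentzian2d(m, (32, 32))
        assert fit.accepted
        assert fit.fwhm_mean == pytest.approx(70.0, rel=0.02)

    def test_center_outside_roi_rejected(self):
        # spot 12 px away from the seed, outside the 7-px ROI half-width
        img = lorentzian_image((64, 64), 44, 32, 5.0, offset=1.0)
        m = MicroscopyImage(img, 10.0, "STED")
        fit = fit_lorentzian2d(m, (32, 32), FitParams(roi_half_width=7))
        assert not fit.accepted
        assert fit.reject_reason in ("center_outside_roi", "uncertainty_exceeded",
                                     "fit_failed", "negative_amplitude")

    def test_high_noise_uncertainty_rejection(self):
        rng = np.random.default_rng(11)
        # weak spot buried in noise: width uncertainty above 60%
        img = lorentzian_image((64, 64), 32, 32, 5.0, amp=0.5, offset=100.0)
        noisy = rng.poisson(img).astype(float)
        m = MicroscopyImage(noisy, 10.0, "STED")
        fit = fit_lorentzian2d(m, (32, 32))
        assert not fit.accepted

    def test_translation_equivariance(self):
        img = lorentzian_image((96, 96), 40, 36, 6.0)
        m1 = MicroscopyImage(img, 10.0, "STED")
        m2 = MicroscopyImage(np.roll(np.roll(img, 7, axis=0), 5, axis=1),
                             10.0, "STED")
        f1 = fit_lorentzian2d(m1, (40, 36))
        f2 = fit_lorentzian2d(m2, (45, 43))
        assert f1.accepted and f2.accepted
        assert f2.center_px[0] - f1.center_px[0] == pytest.approx(5, abs=1e-4)
        assert f2.center_px[1] - f1.center_px[1] == pytest.approx(7, abs=1e-4)
        assert f2.fwhm_mean == pytest.approx(f1.fwhm_mean, rel=1e-6)

    def test_intensity_scale_invariance_of_width(self):
        img = lorentzian_image((64, 64), 32, 32, 6.0)
        f1 = fit_lorentzian2d(MicroscopyImage(img, 10.0, "STED"), (32, 32))
        f2 = fit_lorentzian2d(MicroscopyImage(img * 37.0, 10.0, "STED"),
                              (32, 32))
        assert f2.fwhm_mean == pytest.approx(f1.fwhm_mean, rel=1e-6)
        assert f2.amplitude == pytest.approx(37.0 * f1.amplitude, rel=1e-6)


class TestSegmentation:
    def test_five_spots_then_termination(self):
        rng = np.random.default_rng(0)
        img = np.full((200, 200), 5.0)
        for cx, cy in [(40, 40), (40, 160), (160, 40), (160, 160), (100, 100)]:
            img += lorentzian_image((200, 200), cx, cy, 6.0, amp=2000.0)
        img = rng.poisson(img).astype(float)
        m = MicroscopyImage(img, 10.0, "STED")
        fits = segment_domains_sted(m)
        accepted = [f for f in fits if f.accepted]
        assert len(accepted) == 5
        # termination fired: attempts bounded, not exhaustive segmentation
        assert len(fits) < 40
        centers = sorted((round(f.center_px[0], 0), round(f.center_px[1], 0))
                         for f in accepted)
        assert centers == [(40, 40), (40, 160), (100, 100), (160, 40),
                           (160, 160)]

    def test_brightness_order(self):
        img = np.full((128, 128), 2.0)
        img += lorentzian_image((128, 128), 30, 64, 6.0, amp=500.0)
        img += lorentzian_image((128, 128), 96, 64, 6.0, amp=2000.0)
        m = MicroscopyImage(img, 10.0, "STED")
        fits = segment_domains_sted(m)
        accepted = [f for f in fits if f.accepted]
        assert len(accepted) >= 2
        assert accepted[0].center_px[0] == pytest.approx(96, abs=1)
        assert accepted[1].center_px[0] == pytest.approx(30, abs=1)

    def test_blank_noise_terminates_quickly_with_zero_accepts(self):
        rng = np.random.default_rng(5)
        m = MicroscopyImage(rng.poisson(10.0, (128, 128)).astype(float),
                            10.0, "STED")
        fits = segment_domains_sted(m)
        assert sum(f.accepted for f in fits) == 0
        assert 20 <= len(fits) <= 45  # terminates within a bounded overrun


class TestPairsAndSummary:
    def test_sted_sizes_smaller_than_confocal(self):
        centers = [(400 + 700 * i, 400 + 700 * j)
                   for i in range(3) for j in range(3)]
        conf, sted, _ = simulate_image_pair(centers, 70.0, pixel_nm=10.0,
                                            photon_scale=3000.0,
                                            image_shape=(256, 256), seed=2)
        conf_fits = [fit_gaussian2d(conf, (int(x / 10), int(y / 10)),
                                    FitParams(roi_half_width=12))
                     for x, y in centers]
        sted_fits = segment_domains_sted(sted)
        conf_mean = size_distribution(conf_fits).mean
        sted_mean = size_distribution(sted_fits).mean
        assert sted_mean < conf_mean
        # apparent sizes: sqrt(70^2 + psf^2)
        assert conf_mean == pytest.approx(np.hypot(70, 210), rel=0.05)
        assert sted_mean == pytest.approx(np.hypot(70, 50), rel=0.10)

    def test_size_distribution_excludes_rejected(self):
        img = lorentzian_image((64, 64), 32, 32, 7.0)
        m = MicroscopyImage(img, 10.0, "STED")
        good = fit_lorentzian2d(m, (32, 32))
        bad = fit_lorentzian2d(MicroscopyImage(np.full((64, 64), 3.0), 10.0,
                                               "STED"), (32, 32))
        assert good.accepted and not bad.accepted
        dist = size_distribution([good, bad])
        assert len(dist.fwhm_means) == 1
        assert dist.mean == dist.median == pytest.approx(good.fwhm_mean)
        assert dist.sd == 0.0

    def test_no_accepted_fits_is_error(self):
        bad = fit_lorentzian2d(MicroscopyImage(np.full((64, 64), 3.0), 10.0,
                                               "STED"), (32, 32))
        with pytest.raises(ValueError):
            size_distribution([bad])
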