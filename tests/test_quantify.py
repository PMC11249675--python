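"""Sectioning-curve fits, region statistics and PSF-FWHM extraction."""

import math

import numpy as np
import pytest

from tfsofi import (
    AcquisitionPlan,
    BlinkKinetics,
    CameraModel,
    EmitterSet,
    Excitation,
    NoQualifyingPeaksError,
    PsfStats,
    SectioningCurve,
    TFSectioningModel,
    cumulant2,
    estimate_psf_fwhm,
    fit_gaussian_sectioning,
    fit_tf_sectioning,
    make_gaussian_psf,
    mean_image,
    resolution_improvement,
    simulate_movie,
    summed_signal_curve,
    tf_axial_profile,
)

FWHM_PER_SIGMA = 2 * math.sqrt(2 * math.log(2))


def gaussian_spot(shape, center_rc, fwhm_px, amplitude=100.0, offset=0.0):
    sigma = fwhm_px / FWHM_PER_SIGMA
    r, c = np.mgrid[: shape[0], : shape[1]].astype(float)
    return offset + amplitude * np.exp(
        -((r - center_rc[0]) ** 2 + (c - center_rc[1]) ** 2) / (2 * sigma**2)
    )


class TestSummedSignalCurve:
    def test_uniform_image_has_zero_region_spread(self):
        imgs = [np.full((16, 32), 2.5)] * 3
        curve = summed_signal_curve(imgs, [0.0, 0.1, 0.2], n_regions=8)
        assert np.allclose(curve.signal, 2.5 * 16 * 32 / 8)
        assert np.allclose(curve.uncertainty, 0.0)

    def test_single_position_curve(self, rng):
        curve = summed_signal_curve([rng.random((8, 8))], [0.5], n_regions=4)
        assert len(curve.z_um) == 1 and curve.n_regions == 4

    def test_matches_brute_force_tiling(self, rng):
        img = rng.uniform(0, 9, size=(12, 20))
        curve = summed_signal_curve([img], [0.0], n_regions=8)  # 2 x 4 grid
        sums = [
            img[i * 6 : (i + 1) * 6, j * 5 : (j + 1) * 5].sum()
            for i in range(2)
            for j in range(4)
        ]
        assert curve.signal[0] == pytest.approx(np.mean(sums), rel=1e-12)
        assert curve.uncertainty[0] == pytest.approx(np.std(sums), rel=1e-12)
        # the mean of region sums is 1/n_regions of the total, independent
        # of how region labels are assigned
        assert curve.signal[0] == pytest.approx(img.sum() / 8, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            summed_signal_curve([np.ones((8, 8)), np.ones((8, 9))], [0.0, 0.1])

    def test_untileable_grid_rejected(self):
        with pytest.raises(ValueError):
            summed_signal_curve([np.ones((10, 10))], [0.0], n_regions=8)


def make_tf_curve(a=0.6664, z0=0.0, amplitude=1.0, offset=0.0, noise=0.0, n_regions=8, seed=0):
    model = TFSectioningModel(a_per_um2=a, z0_um=z0, amplitude=amplitude, offset=offset)
    z = np.arange(-6.0, 6.0 + 1e-9, 0.25)
    truth = tf_axial_profile(z, model)
    if noise == 0.0:
        return SectioningCurve(z, truth, np.zeros_like(truth), 1)
    rng = np.random.default_rng(seed)
    regions = truth[None, :] * (1 + noise * rng.standard_normal((n_regions, z.size)))
    return SectioningCurve(z, regions.mean(0), regions.std(0), n_regions)


class TestTfSectioningFit:
    def test_exact_recovery_on_noiseless_curve(self):
        fit = fit_tf_sectioning(make_tf_curve(a=0.6664, z0=0.4, amplitude=3.0, offset=0.2))
        assert fit.success
        assert fit.fwhm_um == pytest.approx(2.0 / math.sqrt(0.6664), rel=1e-6)
        assert fit.parameters["z0_um"] == pytest.approx(0.4, abs=1e-6)
        assert fit.parameters["amplitude"] == pytest.approx(3.0, rel=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_constant_shift_moves_only_the_offset(self):
        base = make_tf_curve()
        shifted = SectioningCurve(base.z_um, base.signal + 5.0, base.uncertainty, base.n_regions)
        f0, f1 = fit_tf_sectioning(base), fit_tf_sectioning(shifted)
        assert f1.parameters["offset"] == pytest.approx(f0.parameters["offset"] + 5.0, abs=1e-6)
        assert f1.fwhm_um == pytest.approx(f0.fwhm_um, rel=1e-9)

    def test_noisy_recovery_within_printed_uncertainty(self):
        # 5% multiplicative noise, 8 regions: each seed recovers the
        # 2.45 um width well within the +/-0.3 um scale
        truth = 2.0 / math.sqrt(0.6664)
        for seed in range(20):
            fit = fit_tf_sectioning(make_tf_curve(noise=0.05, seed=seed))
            assert fit.success
            assert abs(fit.fwhm_um - truth) < 0.3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_tf_sectioning(SectioningCurve([0.0, 1.0], [1.0, 0.5], [0.0, 0.0], 1))


class TestGaussianSectioningFit:
    @staticmethod
    def gaussian_curve(sigma=0.204, z0=0.0, amplitude=2.0, offset=0.1):
        z = np.arange(-1.5, 1.5 + 1e-9, 0.05)
        y = offset + amplitude * np.exp(-((z - z0) ** 2) / (2 * sigma**2))
        return SectioningCurve(z, y, np.zeros_like(y), 1)

    def test_exact_recovery_and_fwhm_convention(self):
        fit = fit_gaussian_sectioning(self.gaussian_curve(sigma=0.204))
        assert fit.success
        assert fit.fwhm_um == pytest.approx(FWHM_PER_SIGMA * 0.204, rel=1e-6)
        assert fit.fwhm_um == pytest.approx(0.480, abs=1e-3)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_curve_centres_at_symmetry_point(self):
        fit = fit_gaussian_sectioning(self.gaussian_curve(z0=0.25))
        assert fit.parameters["z0_um"] == pytest.approx(0.25, abs=1e-9)


class TestEstimatePsfFwhm:
    def test_single_spot_recovery(self):
        fwhm_px = 274.0 / 46.0
        img = gaussian_spot((41, 41), (20.3, 19.6), fwhm_px)
        stats = estimate_psf_fwhm(img, 46.0, min_separation_nm=500.0)
        assert stats.n_emitters == 1
        assert stats.mean_fwhm_nm == pytest.approx(274.0, rel=0.01)

    def test_intensity_scale_invariance(self):
        img = gaussian_spot((41, 41), (20.0, 20.0), 5.0)
        a = estimate_psf_fwhm(img, 46.0)
        b = estimate_psf_fwhm(10.0 * img, 46.0)
        assert b.mean_fwhm_nm == pytest.approx(a.mean_fwhm_nm, rel=1e-6)

    def test_integer_translation_invariance(self):
        a = estimate_psf_fwhm(gaussian_spot((41, 41), (20.0, 20.0), 5.0), 46.0)
        b = estimate_psf_fwhm(gaussian_spot((41, 41), (14.0, 26.0), 5.0), 46.0)
        assert b.mean_fwhm_nm == pytest.approx(a.mean_fwhm_nm, rel=1e-6)

    def test_multiple_well_separated_spots(self):
        img = np.zeros((64, 64))
        for rc in [(12, 12), (12, 50), (50, 12), (50, 50)]:
            img += gaussian_spot((64, 64), rc, 5.0)
        stats = estimate_psf_fwhm(img, 46.0, min_separation_nm=500.0)
        assert stats.n_emitters == 4
        assert stats.std_fwhm_nm < 0.02 * stats.mean_fwhm_nm

    def test_flat_image_raises_explicit_empty_result(self):
        with pytest.raises(NoQualifyingPeaksError):
            estimate_psf_fwhm(np.zeros((32, 32)), 46.0)

    def test_close_pair_keeps_only_the_brighter(self):
        img = gaussian_spot((64, 64), (30, 30), 5.0, amplitude=100.0)
        img += gaussian_spot((64, 64), (30, 36), 5.0, amplitude=50.0)
        img += gaussian_spot((64, 64), (12, 12), 5.0, amplitude=80.0)
        stats = estimate_psf_fwhm(img, 46.0, min_separation_nm=400.0)
        rows = [round(r) for r, _ in stats.details["centers_px"]]
        assert 30 in rows and len(stats.fwhm_nm) == 2


class TestSofiResolutionShrink:
    def test_cumulant_image_psf_is_sqrt2_narrower(self):
        # a single blinking emitter, no camera noise: the lag-0 variance
        # image is the squared PSF, whose fitted FWHM is 274/sqrt(2)
        psf = make_gaussian_psf(274.0, 680.0)
        plan = AcquisitionPlan(n_frames=200, frame_shape=(48, 48), pixel_size_nm=46.0, seed=21)
        emitter = EmitterSet([0.0], [0.0], [0.0], [2000.0])
        stack = simulate_movie(
            emitter, plan, 0.0, psf, Excitation("widefield"), CameraModel.noiseless(),
            BlinkKinetics(0.5, 0.5),
        )
        mean_fwhm = estimate_psf_fwhm(mean_image(stack), 46.0).mean_fwhm_nm
        sofi_fwhm = estimate_psf_fwhm(cumulant2(stack).image, 46.0).mean_fwhm_nm
        assert mean_fwhm == pytest.approx(274.0, rel=0.03)
        assert sofi_fwhm / mean_fwhm == pytest.approx(1 / math.sqrt(2), rel=0.03)


class TestResolutionImprovement:
    def stats(self, mean, std):
        return PsfStats(np.array([mean]), mean, std, 1)

    def test_identical_inputs_give_unity(self):
        s = self.stats(200.0, 10.0)
        ratio, err = resolution_improvement(s, s)
        assert ratio == 1.0

    def test_printed_values_consistent_with_sqrt2(self):
        ratio, err = resolution_improvement(self.stats(274.0, 18.0), self.stats(199.0, 12.0))
        assert ratio == pytest.approx(1.38, abs=0.005)
        assert abs(ratio - math.sqrt(2)) < err

    def test_invariant_under_common_rescaling(self):
        r1, _ = resolution_improvement(self.stats(274.0, 18.0), self.stats(199.0, 12.0))
        r2, _ = resolution_improvement(self.stats(2740.0, 180.0), self.stats(1990.0, 120.0))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            resolution_improvement(self.stats(274.0, 18.0), self.stats(0.0, 0.0))
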