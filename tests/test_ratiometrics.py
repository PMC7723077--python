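"""Background subtraction, bleedthrough correction, and ROI emission
ratios, checked against the forward model's hidden truth."""
import numpy as np
import pytest

from rootpi.calibration import concentration_from_ratio, fit_isotherm
from rootpi.ratiometrics import (
    BackgroundEstimate,
    CorrectionCoefficients,
    RawFrameSet,
    estimate_background,
    estimate_correction_coefficients,
    roi_emission_ratio,
    sensitized_emission,
)
from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.datasets import make_calibration_dataset
from rootpi.synth.imaging import render_frameset


def _uniform_frameset(value: float, shape=(8, 8)) -> RawFrameSet:
    img = np.full(shape, value, dtype=float)
    return RawFrameSet(dd=img.copy(), da=img.copy(), aa=img.copy())


class TestBackground:
    def test_uniform_reference(self):
        bg = estimate_background(_uniform_frameset(100.0))
        assert (bg.dd, bg.da, bg.aa) == (100.0, 100.0, 100.0)

    def test_zero_reference_makes_subtraction_identity(self):
        bg = estimate_background(_uniform_frameset(0.0))
        frames = _uniform_frameset(42.0)
        coeff = CorrectionCoefficients(alpha=0.0, beta=0.0)
        f_sens, clamped = sensitized_emission(frames, bg, coeff)
        assert np.array_equal(f_sens, frames.da)
        assert clamped == 0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(
                _uniform_frameset(1.0), region=np.zeros((8, 8), dtype=bool)
            )

    def test_noisy_reference_within_3_sem(self, sensor):
        acq = AcquisitionModel(background_mean=(120.0, 120.0, 120.0), read_noise_sd=5.0)
        mask = np.zeros((64, 64), dtype=bool)
        res = render_frameset(0.0, mask, sensor, acq, seed=11)
        bg = estimate_background(res.blank)
        sem = np.sqrt(120.0 + 25.0) / 64.0  # Poisson + read variance over 4096 px
        for value in (bg.dd, bg.da, bg.aa):
            assert abs(value - 120.0) < 3 * sem


class TestCorrectionCoefficients:
    def test_exact_slopes_on_pure_references(self):
        dd = np.full((20, 20), 500.0)
        donor = RawFrameSet(dd=dd, da=0.3 * dd, aa=np.zeros_like(dd))
        acceptor = RawFrameSet(dd=np.zeros_like(dd), da=0.1 * dd, aa=dd)
        bg = BackgroundEstimate(dd=0.0, da=0.0, aa=0.0)
        coeff = estimate_correction_coefficients(donor, acceptor, bg)
        assert coeff.alpha == pytest.approx(0.3)
        assert coeff.beta == pytest.approx(0.1)

    def test_generator_references_within_5pct(self, sensor, default_acq, small_mask):
        res = render_frameset(5.0, small_mask, sensor, default_acq, seed=3)
        bg = estimate_background(res.blank)
        coeff = estimate_correction_coefficients(res.donor_only, res.acceptor_only, bg)
        assert coeff.alpha == pytest.approx(sensor.alpha_true, rel=0.05)
        assert coeff.beta == pytest.approx(sensor.beta_true, rel=0.05)

    def test_insufficient_pixels_errors(self):
        tiny = _uniform_frameset(0.0, shape=(2, 2))
        bg = BackgroundEstimate(dd=0.0, da=0.0, aa=0.0)
        with pytest.raises(ValueError, match="above-floor"):
            estimate_correction_coefficients(tiny, tiny, bg)


class TestSensitizedEmission:
    def test_zero_on_single_fluorophore_references(self, sensor, noiseless_acq, small_mask):
        res = render_frameset(5.0, small_mask, sensor, noiseless_acq)
        bg = estimate_background(res.blank)
        coeff = CorrectionCoefficients(alpha=sensor.alpha_true, beta=sensor.beta_true)
        for ref in (res.donor_only, res.acceptor_only):
            f_sens, _ = sensitized_emission(ref, bg, coeff)
            assert np.allclose(f_sens, 0.0, atol=1e-9)

    def test_shape_mismatch_errors(self, sensor, noiseless_acq, small_mask):
        res = render_frameset(5.0, small_mask, sensor, noiseless_acq)
        bg = estimate_background(res.blank)
        with pytest.raises(ValueError, match="ROI shape"):
            roi_emission_ratio(
                res.frames, np.ones((4, 4), bool), bg,
                CorrectionCoefficients(0.3, 0.1),
            )


class TestRoiRatio:
    def _measure(self, c, sensor, acq, mask, seed=0, floor=None):
        res = render_frameset(c, mask, sensor, acq, seed=seed)
        bg = estimate_background(res.blank)
        coeff = estimate_correction_coefficients(res.donor_only, res.acceptor_only, bg)
        return roi_emission_ratio(
            res.frames, mask, bg, coeff,
            intensity_floor=acq.floor if floor is None else floor,
        )

    def test_noiseless_midpoint_at_kd(self, sensor, noiseless_acq, small_mask):
        meas = self._measure(7.4, sensor, noiseless_acq, small_mask)
        assert meas.ratio == pytest.approx(2.0, abs=1e-12)

    def test_all_below_floor_flags_low_signal(self, sensor, noiseless_acq, small_mask):
        meas = self._measure(7.4, sensor, noiseless_acq, small_mask,
                             floor=10 * noiseless_acq.photon_scale)
        assert meas.ratio is None
        assert "low-signal" in meas.qc_flags
        assert not meas.ok

    def test_linearity_under_channel_scaling(self, sensor, noiseless_acq, small_mask):
        res = render_frameset(10.0, small_mask, sensor, noiseless_acq)
        bg = estimate_background(res.blank)
        coeff = CorrectionCoefficients(alpha=sensor.alpha_true, beta=sensor.beta_true)
        base = roi_emission_ratio(res.frames, small_mask, bg, coeff)
        scaled_frames = RawFrameSet(
            dd=3.0 * res.frames.dd, da=3.0 * res.frames.da, aa=3.0 * res.frames.aa
        )
        scaled_bg = BackgroundEstimate(dd=3.0 * bg.dd, da=3.0 * bg.da, aa=3.0 * bg.aa)
        scaled = roi_emission_ratio(scaled_frames, small_mask, scaled_bg, coeff)
        assert scaled.ratio == pytest.approx(base.ratio, rel=1e-12)

    def test_two_zone_scene_recovers_truth(self, sensor, default_acq):
        """ROI ratios within 2% and inverted concentrations within 5% of
        the generator truth on a two-zone scene at default noise."""
        mask = np.zeros((24, 24), dtype=bool)
        mask[2:-2, 2:-2] = True
        pi_field = np.where(np.arange(24)[None, :] < 12, 4.0, 10.0) * np.ones((24, 1))
        res = render_frameset(pi_field, mask, sensor, default_acq, seed=21)
        bg = estimate_background(res.blank)
        coeff = estimate_correction_coefficients(res.donor_only, res.acceptor_only, bg)
        table, _ = make_calibration_dataset(
            sensor, [0, 1, 3, 7.4, 12, 20, 30], n_rep=8, noise_sd_ratio=0.0, seed=1
        )
        fit = fit_isotherm(table)
        for half, truth in ((np.s_[:, :12], 4.0), (np.s_[:, 12:], 10.0)):
            roi = np.zeros_like(mask)
            roi[half] = True
            roi &= mask
            meas = roi_emission_ratio(res.frames, roi, bg, coeff, default_acq.floor)
            assert meas.ratio == pytest.approx(float(sensor.ratio(truth)), rel=0.02)
            c_est = float(concentration_from_ratio(meas.ratio, fit))
            assert c_est == pytest.approx(truth, rel=0.05)

    def test_null_sensor_scene_independent_of_pi(self, default_acq):
        """Control-sensor scenes show no dependence of ratio on the true
        Pi field (slope indistinguishable from zero)."""
        from scipy.stats import linregress

        from rootpi.synth.sensor import SensorModel

        null = SensorModel(kd=7.4, r_min=1.0, r_max=3.0, mode="null")
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:-2, 2:-2] = True
        truths, ratios = [], []
        for i, c in enumerate(np.linspace(0.5, 20, 24)):
            res = render_frameset(c, mask, null, default_acq, seed=100 + i)
            bg = estimate_background(res.blank)
            coeff = estimate_correction_coefficients(
                res.donor_only, res.acceptor_only, bg
            )
            meas = roi_emission_ratio(res.frames, mask, bg, coeff, default_acq.floor)
            truths.append(c)
            ratios.append(meas.ratio)
        reg = linregress(truths, ratios)
        assert reg.pvalue > 0.05
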