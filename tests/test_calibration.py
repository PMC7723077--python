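"""Isotherm fitting, inversion, saturation gating, and uncertainty."""
import numpy as np
import pandas as pd
import pytest

from rootpi.calibration import (
    CalibrationFit,
    assay_range,
    concentration_from_ratio,
    fit_isotherm,
    kd_relative_error,
    ratio_to_concentration,
    saturation_to_concentration,
)
from rootpi.synth.datasets import make_calibration_dataset
from rootpi.synth.sensor import SensorModel

LEVELS = [0.0, 1.0, 3.0, 7.4, 12.0, 20.0, 30.0]


def _noiseless_fit(sensor) -> CalibrationFit:
    table, _ = make_calibration_dataset(sensor, LEVELS, n_rep=2, noise_sd_ratio=0.0, seed=0)
    return fit_isotherm(table)


class TestFitIsotherm:
    def test_noiseless_exact_recovery(self, sensor):
        fit = _noiseless_fit(sensor)
        assert fit.kd == pytest.approx(7.4, rel=1e-9)
        assert fit.r_min == pytest.approx(1.0, rel=1e-9)
        assert fit.r_max == pytest.approx(3.0, rel=1e-9)

    def test_zero_dynamic_range_errors(self):
        table = pd.DataFrame(
            {"concentration_mM": LEVELS, "ratio": [2.0] * len(LEVELS), "replicate": 1}
        )
        with pytest.raises(ValueError, match="not all equal"):
            fit_isotherm(table)

    def test_too_few_levels_errors(self):
        table = pd.DataFrame(
            {"concentration_mM": [0, 5, 10], "ratio": [1.0, 1.5, 1.8], "replicate": 1}
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_isotherm(table)

    def test_aggregated_weighted_input(self, sensor):
        table = pd.DataFrame(
            {
                "concentration_mM": LEVELS,
                "ratio_mean": [float(sensor.ratio(c)) for c in LEVELS],
                "ratio_sd": [0.05] * len(LEVELS),
                "n": [8] * len(LEVELS),
            }
        )
        fit = fit_isotherm(table)
        assert fit.fit_diagnostics["weighted"]
        assert fit.kd == pytest.approx(7.4, rel=1e-6)

    def test_kd_invariant_under_affine_ratio_rescaling(self, sensor):
        table, _ = make_calibration_dataset(sensor, LEVELS, 8, 0.05, seed=9)
        fit = fit_isotherm(table)
        rescaled = table.assign(ratio=2.5 * table["ratio"] + 0.7)
        fit2 = fit_isotherm(rescaled)
        assert fit2.kd == pytest.approx(fit.kd, rel=1e-6)
        assert fit2.r_min == pytest.approx(2.5 * fit.r_min + 0.7, rel=1e-6)

    def test_recovery_coverage_small(self, sensor):
        """Fitted Kd covers truth within 2 SE in most noisy replicates
        (small version of the full 200-seed study)."""
        hits = 0
        for seed in range(40):
            table, _ = make_calibration_dataset(sensor, LEVELS, 8, 0.05, seed=seed)
            fit = fit_isotherm(table)
            hits += abs(fit.kd - sensor.kd) <= 2 * fit.kd_se
        assert hits >= 36


class TestInversion:
    def test_round_trip_identity(self, sensor):
        fit = _noiseless_fit(sensor)
        for c in (2.0, 5.0, 10.0, 15.0):
            est = ratio_to_concentration(float(sensor.ratio(c)), fit)
            assert est.concentration == pytest.approx(c, rel=1e-9)

    def test_r_min_censors_below(self, sensor):
        fit = _noiseless_fit(sensor)
        est = ratio_to_concentration(fit.r_min, fit)
        assert est.concentration == 0.0
        assert est.censor == "below"
        assert not est.in_range

    def test_r_max_censors_above_at_bound(self, sensor):
        fit = _noiseless_fit(sensor)
        rng = assay_range(fit)
        est = ratio_to_concentration(fit.r_max + 0.5, fit, rng)
        assert est.concentration == pytest.approx(rng.c_hi)
        assert est.censor == "above"

    def test_midpoint_maps_to_kd(self, sensor):
        fit = _noiseless_fit(sensor)
        est = ratio_to_concentration((fit.r_min + fit.r_max) / 2, fit)
        assert est.concentration == pytest.approx(fit.kd, rel=1e-9)
        assert est.saturation == pytest.approx(0.5, rel=1e-9)
        assert est.in_range

    def test_monotone_in_ratio(self, sensor):
        fit = _noiseless_fit(sensor)
        ratios = np.linspace(fit.r_min + 1e-6, fit.r_max - 1e-6, 300)
        conc = concentration_from_ratio(ratios, fit)
        assert np.all(np.diff(conc) > 0)

    def test_rel_error_attached(self, sensor):
        table, _ = make_calibration_dataset(sensor, LEVELS, 8, 0.05, seed=4)
        fit = fit_isotherm(table)
        est = ratio_to_concentration(2.0, fit)
        assert est.rel_error == pytest.approx(fit.kd_rel_err)
        assert est.rel_error_delta is not None and est.rel_error_delta > 0


class TestSaturation:
    def test_half_saturation(self):
        assert saturation_to_concentration(0.5, 7.4) == pytest.approx(7.4)

    @pytest.mark.parametrize("s, expected", [(0.2, 1.85), (0.8, 29.6)])
    def test_assay_bounds_from_isotherm(self, s, expected):
        assert saturation_to_concentration(s, 7.4) == pytest.approx(expected)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.7])
    def test_out_of_domain_errors(self, s):
        with pytest.raises(ValueError, match="saturation"):
            saturation_to_concentration(s, 7.4)


class TestKdRelativeError:
    def test_reported_value(self):
        assert round(kd_relative_error(7.4, 1.7)) == 23

    def test_smaller_se(self):
        assert kd_relative_error(7.4, 0.5) == pytest.approx(6.8, abs=0.05)

    def test_zero_se(self):
        assert kd_relative_error(7.4, 0.0) == 0.0


class TestAssayRange:
    def test_defaults_from_isotherm(self, sensor):
        fit = _noiseless_fit(sensor)
        rng = assay_range(fit)
        assert rng.c_lo == pytest.approx(1.85, rel=1e-6)
        assert rng.c_hi == pytest.approx(29.6, rel=1e-6)
        assert rng.source == "isotherm"

    def test_explicit_override_stored_verbatim(self, sensor):
        fit = _noiseless_fit(sensor)
        rng = assay_range(fit, c_lo=1.6, c_hi=19.0)
        assert (rng.c_lo, rng.c_hi) == (1.6, 19.0)
        assert rng.source == "config"

    def test_degenerate_saturation_errors(self, sensor):
        fit = _noiseless_fit(sensor)
        with pytest.raises(ValueError, match="s_lo"):
            assay_range(fit, s_lo=0.5, s_hi=0.5)


class TestPhysicalModeRobustness:
    def test_isotherm_fit_tolerates_occupancy_hyperbolic_sensor(self):
        """Fitting the isotherm to data from a donor-quenching sensor
        (ratio hyperbolic in occupancy, not isotherm-shaped) still
        converges with endpoints near the true ratio bounds."""
        phys = SensorModel(kd=7.4, r_min=1.0, r_max=3.0, mode="physical")
        table, _ = make_calibration_dataset(
            phys, [0.0, 1.0, 3.0, 7.4, 12.0, 20.0, 30.0, 60.0], 8, 0.02, seed=3
        )
        fit = fit_isotherm(table)
        assert fit.r_min == pytest.approx(1.0, abs=0.15)
        assert fit.kd > 0
        # the mis-specified model shifts the apparent kd upward
        assert fit.kd > 7.4
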