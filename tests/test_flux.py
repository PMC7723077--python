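"""Flux decomposition: plateau detection, uptake arithmetic,
sequestration contrast, and medium-depletion mass balance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rootpi.calibration import fit_isotherm
from rootpi.flux import (
    KineticTrace,
    amount_from_delta,
    detectability,
    medium_depletion_uptake,
    percent_change_vs_control,
    plateau_change,
    sequestration_estimate,
    uptake_delta,
)
from rootpi.synth.datasets import make_calibration_dataset, make_depletion_series
from rootpi.synth.imaging import KineticSpec, simulate_kinetic_series
from rootpi.synth.sensor import IN_VITRO_SENSOR
from rootpi.workflows import measure_kinetic_trace


def _trace(times, conc, **kw):
    return KineticTrace(time=np.asarray(times), concentration=np.asarray(conc), **kw)


class TestPlateauChange:
    def test_constant_trace_has_zero_delta(self):
        t = np.arange(-3, 20.5, 0.5)
        res = plateau_change(_trace(t, np.full(t.size, 5.0)))
        assert res.delta_c == 0.0
        assert "no-rise" in res.qc_flags

    def test_closed_form_exponential(self):
        """2.0·(1 − e^(−t/2)) recovers delta 2.0 with plateau inside 10 s."""
        t = np.arange(-3, 20.5, 0.5)
        c = 4.0 + np.where(t < 0, 0.0, 2.0 * (1 - np.exp(-np.clip(t, 0, None) / 2.0)))
        res = plateau_change(_trace(t, c))
        assert res.delta_c == pytest.approx(2.0, rel=0.01)
        assert 4.0 <= res.t_plateau <= 10.0

    def test_short_trace_errors(self):
        t = np.arange(-3, 10.0, 0.5)
        with pytest.raises(ValueError, match="15 s"):
            plateau_change(_trace(t, np.full(t.size, 1.0)))

    def test_needs_baseline_points(self):
        t = np.arange(-0.5, 20.0, 0.5)
        with pytest.raises(ValueError, match="baseline"):
            plateau_change(_trace(t, np.full(t.size, 1.0)))

    def test_recovers_generated_delta(self, sensor, default_acq, small_mask):
        """Full-chain delta recovery within 10% of truth at default noise."""
        table, _ = make_calibration_dataset(
            sensor, [0, 1, 3, 7.4, 12, 20, 30], 8, 0.0, seed=0
        )
        fit = fit_isotherm(table)
        spec = KineticSpec(c_baseline=4.15, delta_recycling=0.47, delta_uptake=0.84)
        errors = []
        for seed in range(10):
            series = simulate_kinetic_series(
                small_mask, sensor, spec, "CN_plus_Pi", default_acq, seed=seed
            )
            trace = measure_kinetic_trace(series, fit, default_acq)
            res = plateau_change(trace)
            errors.append(abs(res.delta_c - spec.delta_for("CN_plus_Pi"))
                          / spec.delta_for("CN_plus_Pi"))
        assert np.median(errors) < 0.10


class TestUptakeArithmetic:
    def test_equal_deltas_cancel(self):
        d, flags = uptake_delta(0.5, 0.5)
        assert d == 0.0 and not flags

    def test_subtraction(self):
        d, _ = uptake_delta(1.31, 0.47)
        assert d == pytest.approx(0.84)

    def test_negative_retained_with_flag(self):
        d, flags = uptake_delta(0.4, 0.5)
        assert d == pytest.approx(-0.1)
        assert "negative-delta" in flags

    @pytest.mark.parametrize(
        "delta, volume, expected",
        [(0.84, 192.0, 0.16), (0.78, 597.0, 0.47), (1.0, 1000.0, 1.0)],
    )
    def test_amount_worked_examples(self, delta, volume, expected):
        amount, rate = amount_from_delta(delta, volume)
        assert round(amount, 2) == expected
        assert rate == pytest.approx(amount / 8.0)

    @settings(max_examples=40, derandomize=True)
    @given(d=st.floats(0, 5), v=st.floats(0, 5000), k=st.floats(0.1, 10))
    def test_amount_linear_in_both_arguments(self, d, v, k):
        base, _ = amount_from_delta(d, v)
        scaled_d, _ = amount_from_delta(k * d, v)
        scaled_v, _ = amount_from_delta(d, k * v)
        assert scaled_d == pytest.approx(k * base, rel=1e-9, abs=1e-12)
        assert scaled_v == pytest.approx(k * base, rel=1e-9, abs=1e-12)

    def test_sequential_equals_simultaneous_design(self, sensor, default_acq, small_mask):
        """Uptake deltas agree whether CN and Pi arrive together (difference
        of two treatments) or sequentially (Pi added at the CN plateau)."""
        table, _ = make_calibration_dataset(
            sensor, [0, 1, 3, 7.4, 12, 20, 30], 8, 0.0, seed=0
        )
        fit = fit_isotherm(table)
        rec, up = 0.47, 0.84
        sim, seq = [], []
        for seed in range(8):
            spec = KineticSpec(4.15, rec, up)
            cn = measure_kinetic_trace(
                simulate_kinetic_series(small_mask, sensor, spec, "CN",
                                        default_acq, seed=seed),
                fit, default_acq)
            both = measure_kinetic_trace(
                simulate_kinetic_series(small_mask, sensor, spec, "CN_plus_Pi",
                                        default_acq, seed=seed + 100),
                fit, default_acq)
            sim.append(plateau_change(both).delta_c - plateau_change(cn).delta_c)
            # sequential: second addition starts from the CN plateau
            spec_seq = KineticSpec(4.15 + rec, up, 0.0)
            second = measure_kinetic_trace(
                simulate_kinetic_series(small_mask, sensor, spec_seq, "CN",
                                        default_acq, seed=seed + 200),
                fit, default_acq)
            seq.append(plateau_change(second).delta_c)
        assert np.mean(sim) == pytest.approx(np.mean(seq), abs=0.05)


class TestDetectability:
    def test_large_cell_hides_uptake(self):
        implied, detectable = detectability(0.17, 1735.0)
        assert implied == pytest.approx(0.098, abs=0.001)
        assert not detectable

    def test_small_cell_resolves_same_amount(self):
        implied, detectable = detectability(0.17, 403.0, floor_delta_mm=0.4)
        assert implied == pytest.approx(0.42, abs=0.005)
        assert detectable

    def test_zero_floor_always_detectable(self):
        assert detectability(1e-6, 5000.0, floor_delta_mm=0.0)[1]


class TestSequestration:
    def test_identical_genotypes_give_zero(self):
        res = sequestration_estimate(0.8, 0.8, zone="MZ")
        assert res.sequestration_delta == 0.0

    def test_zone_mismatch_errors(self):
        with pytest.raises(ValueError, match="matched zones"):
            sequestration_estimate(0.5, 0.8, zone="MZ", zone_mutant="TZ")

    def test_negative_flagged(self):
        res = sequestration_estimate(0.9, 0.7, zone="TZ")
        assert "negative-sequestration" in res.qc_flags

    def test_error_propagation(self):
        res = sequestration_estimate(0.5, 0.9, zone="MZ", se_wt=0.03, se_mutant=0.04)
        assert res.se == pytest.approx(0.05)


class TestDepletion:
    def test_flat_series_zero_uptake(self):
        table, _ = make_depletion_series(uptake_rate_nmol_per_seedling_h=0.0,
                                         noise_sd_ratio=0.0)
        series = medium_depletion_uptake(table, None, 0.5, 12)
        assert np.allclose(series.mean_uptake, 0.0)

    def test_full_depletion_per_seedling(self):
        table, _ = make_depletion_series(
            c0=0.25, well_volume_ml=0.5, n_seedlings=12,
            uptake_rate_nmol_per_seedling_h=10.0, duration_h=6.0,
        )
        series = medium_depletion_uptake(table, None, 0.5, 12)
        assert series.mean_uptake[-1] == pytest.approx(10.4, abs=0.05)

    def test_mass_balance_conserved(self):
        table, _ = make_depletion_series(uptake_rate_nmol_per_seedling_h=1.5)
        series = medium_depletion_uptake(table, None, 0.5, 12)
        initial_nmol = 0.25 * 0.5 * 1000.0
        for well in series.cumulative_uptake.columns:
            total = (series.cumulative_uptake[well] * 12
                     + series.medium_concentration[well] * 0.5 * 1000.0)
            assert np.allclose(total, initial_nmol, rtol=1e-9)

    def test_ratio_path_recovers_rate(self):
        """Noisy emission-ratio input inverted through the in vitro fit
        recovers the uptake rate within 10%."""
        rate = 1.5
        table, _ = make_depletion_series(
            uptake_rate_nmol_per_seedling_h=rate, noise_sd_ratio=0.01, seed=8
        )
        cal, _ = make_calibration_dataset(
            IN_VITRO_SENSOR, [0.0, 0.02, 0.05, 0.08, 0.15, 0.3], 8, 0.01, seed=9
        )
        fit = fit_isotherm(cal)
        series = medium_depletion_uptake(
            table.drop(columns="concentration_mM"), fit, 0.5, 12
        )
        slope = np.polyfit(series.time, series.mean_uptake, 1)[0]
        assert slope == pytest.approx(rate, rel=0.10)

    def test_rising_concentration_flagged(self):
        table, _ = make_depletion_series(uptake_rate_nmol_per_seedling_h=0.5)
        table.loc[table.index[-1], "concentration_mM"] = 0.30  # above C(0)
        series = medium_depletion_uptake(table, None, 0.5, 12)
        assert "evaporation/contamination" in series.qc_flags


class TestPercentChange:
    def test_equal_is_zero(self):
        assert percent_change_vs_control(5.0, 5.0) == 0.0

    def test_signs(self):
        assert percent_change_vs_control(7.4, 10.0) == pytest.approx(-26.0)
        assert percent_change_vs_control(12.0, 10.0) == pytest.approx(20.0)

    def test_zero_control_errors(self):
        with pytest.raises(ValueError):
            percent_change_vs_control(1.0, 0.0)
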