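"""Composed workflows: full-chain measurement of synthetic datasets and
the parameter-recovery studies that validate each stage.

Everything here runs the real analysis path — background estimation,
bleedthrough correction, ratio measurement, isotherm inversion, plateau
detection, voxel-count volumetry — on data from the forward model, then
scores the results against the generator's hidden truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rootpi import reference
from rootpi.calibration import (
    CalibrationFit,
    assay_range,
    concentration_from_ratio,
    fit_isotherm,
)
from rootpi.flux import KineticTrace, decompose_fluxes, sequestration_estimate
from rootpi.ratiometrics import (
    estimate_background,
    estimate_correction_coefficients,
    roi_emission_ratio,
)
from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.datasets import make_calibration_dataset
from rootpi.synth.geometry import make_cell_geometry
from rootpi.synth.imaging import (
    KineticSeriesResult,
    draw_kinetic_spec,
    simulate_kinetic_series,
)
from rootpi.synth.sensor import DEFAULT_SENSOR, SensorModel
from rootpi.volumetry import threshold_stack, voxel_volume, ZStack


def fit_reference_calibration(
    sensor: SensorModel = DEFAULT_SENSOR,
    seed: int = 0,
    noise_sd_ratio: float = 0.05,
) -> CalibrationFit:
    """Fit an isotherm to a synthetic injection-calibration series under
    the standard design (7 levels spanning 0-30 mM, 8 replicates)."""
    table, _ = make_calibration_dataset(
        sensor,
        [0.0, 1.0, 3.0, sensor.kd, 12.0, 20.0, 30.0],
        n_rep=8,
        noise_sd_ratio=noise_sd_ratio,
        seed=seed,
    )
    return fit_isotherm(table)


def measure_kinetic_trace(
    series: KineticSeriesResult,
    fit: CalibrationFit,
    acq: AcquisitionModel,
    **trace_kwargs,
) -> KineticTrace:
    """Convert a rendered time-lapse series into a concentration trace via
    the full correction/calibration chain."""
    bg = estimate_background(series.blank)
    coeff = estimate_correction_coefficients(series.donor_only, series.acceptor_only, bg)
    ratios = []
    for frames in series.framesets:
        meas = roi_emission_ratio(frames, series.mask, bg, coeff, intensity_floor=acq.floor)
        ratios.append(meas.ratio)
    conc = concentration_from_ratio(np.asarray(ratios, dtype=float), fit)
    return KineticTrace(
        time=series.times,
        concentration=conc,
        treatment=series.treatment,
        **trace_kwargs,
    )


def _measured_volume(mask3d: np.ndarray, acq: AcquisitionModel, rng: np.random.Generator) -> float:
    """Voxel-count volumetry of a rendered z-stack of the cell's cytosol."""
    mask3d = np.pad(mask3d, ((1, 1), (3, 3), (3, 3)))
    intensity = acq.acquire(1000.0 * mask3d.astype(float), "aa", rng)
    stack = ZStack(intensity=intensity, voxel_size=acq.voxel_volume_um3)
    cell = threshold_stack(stack, method="per_slice_otsu")
    return voxel_volume(cell, acq.voxel_volume_um3).volume_um3


@dataclass
class FluxRecoveryCell:
    zone: str
    true_recycling: float
    true_uptake: float
    true_volume_um3: float
    true_amount_fmol: float
    est_recycling: float
    est_uptake: float
    est_volume_um3: float
    est_amount_fmol: float
    t_plateau_true: float
    t_plateau_est: float


def recover_flux_cell(
    zone: str,
    seed: int,
    sensor: SensorModel,
    fit: CalibrationFit,
    acq: AcquisitionModel | None = None,
    sequestration_fraction: float = 0.0,
    condition: str = "starved",
    mask_shape: tuple = (16, 16),
) -> FluxRecoveryCell:
    """Simulate and fully re-analyze one cell of the cyanide assay.

    Truth is drawn from the measured magnitude ranges for the zone:
    recycling delta from the per-zone default, uptake delta from the
    reported mean ± sd, cytosolic volume from the per-zone volume table.
    """
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(seed)
    up_mean, up_sd = reference.UPTAKE_DELTA_MM[zone]
    rec = reference.RECYCLING_DELTA_MM[zone]
    spec = draw_kinetic_spec(
        rng,
        c_baseline=reference.zone_mean_pi(zone, condition),
        delta_recycling=float(np.clip(rng.normal(rec, 0.1 * rec), 0.1, None)),
        delta_uptake=float(np.clip(rng.normal(up_mean, up_sd), 0.05, None)),
        sequestration_fraction=sequestration_fraction,
    )
    geom = make_cell_geometry(zone, condition, acq, rng)
    mask2d = np.zeros(mask_shape, dtype=bool)
    mask2d[2:-2, 2:-2] = True
    traces = {}
    for treatment in ("CN", "CN_plus_Pi"):
        series = simulate_kinetic_series(
            mask2d, sensor, spec, treatment, acq, seed=int(rng.integers(2 ** 31))
        )
        traces[treatment] = measure_kinetic_trace(series, fit, acq, zone=zone)
    vol = _measured_volume(geom.mask, acq, rng)
    result = decompose_fluxes(traces["CN"], traces["CN_plus_Pi"], vol)
    eff_uptake = spec.delta_uptake * (1.0 - spec.sequestration_fraction)
    return FluxRecoveryCell(
        zone=zone,
        true_recycling=spec.delta_recycling,
        true_uptake=eff_uptake,
        true_volume_um3=geom.volume_um3,
        true_amount_fmol=eff_uptake * geom.volume_um3 * 1e-3,
        est_recycling=result.delta_recycling,
        est_uptake=result.delta_uptake,
        est_volume_um3=vol,
        est_amount_fmol=result.uptake_amount,
        t_plateau_true=spec.t_plateau_true,
        t_plateau_est=result.t_plateau,
    )


def flux_recovery_study(
    zones=("LRC", "MZ", "TZ"),
    n_cells: int = 100,
    seed: int = 0,
    sensor: SensorModel = DEFAULT_SENSOR,
) -> pd.DataFrame:
    """Per-cell flux recovery over seeded synthetic cells per zone.

    Runs the full chain (calibration fit included) and returns one row per
    cell with truth and estimates.
    """
    rng = np.random.default_rng(seed)
    fit = fit_reference_calibration(sensor, seed=int(rng.integers(2 ** 31)))
    rows = []
    for zone in zones:
        for _ in range(n_cells):
            cell = recover_flux_cell(zone, int(rng.integers(2 ** 31)), sensor, fit)
            rows.append(vars(cell))
    df = pd.DataFrame(rows)
    df["amount_rel_err"] = (
        (df["est_amount_fmol"] - df["true_amount_fmol"]).abs() / df["true_amount_fmol"]
    )
    return df


def sequestration_grid_study(
    fractions=tuple(np.round(np.linspace(0.0, 0.9, 10), 2)),
    n_cells: int = 6,
    zone: str = "MZ",
    seed: int = 0,
    sensor: SensorModel = DEFAULT_SENSOR,
) -> pd.DataFrame:
    """Genotype-contrast sequestration estimates across a grid of true
    sequestration fractions.

    For each fraction, wild-type cells divert that fraction of uptake to
    the vacuole while sequestration-null cells divert none; the estimate is
    the difference of genotype-mean uptake deltas.
    """
    rng = np.random.default_rng(seed)
    fit = fit_reference_calibration(sensor, seed=int(rng.integers(2 ** 31)))
    rows = []
    for frac in fractions:
        wt = [
            recover_flux_cell(zone, int(rng.integers(2 ** 31)), sensor, fit,
                              sequestration_fraction=float(frac))
            for _ in range(n_cells)
        ]
        mut = [
            recover_flux_cell(zone, int(rng.integers(2 ** 31)), sensor, fit,
                              sequestration_fraction=0.0)
            for _ in range(n_cells)
        ]
        d_wt = float(np.mean([c.est_uptake for c in wt]))
        d_mut = float(np.mean([c.est_uptake for c in mut]))
        est = sequestration_estimate(d_wt, d_mut, zone=zone)
        true_seq = float(np.mean([c.true_uptake for c in mut])) * frac
        rows.append(
            {
                "true_fraction": float(frac),
                "true_sequestration_mM": true_seq,
                "delta_wt": d_wt,
                "delta_mutant": d_mut,
                "estimated_sequestration_mM": est.sequestration_delta,
            }
        )
    return pd.DataFrame(rows)


def replica_separation_study(
    n_seeds: int = 30,
    base_seed: int = 0,
    n_cells_per_zone: int = 20,
) -> pd.DataFrame:
    """Repeat the synthetic replica study across seeds and record whether
    the transition-zone maximum is recovered and Tukey-separated, and
    whether the control-sensor channel stays spatially flat."""
    from rootpi.pipeline import StudyConfig, run_pipeline

    rows = []
    for i in range(n_seeds):
        seed = (base_seed + 7919 * i) % (2 ** 31)
        bundle = run_pipeline(
            StudyConfig(seed=seed, n_cells_per_zone=n_cells_per_zone).validate()
        )
        letters = bundle["tukey"].letters
        tz_sep = all(
            not (set(letters["TZ"]) & set(letters[z])) for z in letters if z != "TZ"
        )
        means = bundle["cells"].groupby("zone")["concentration_mM"].mean()
        rows.append(
            {
                "seed": seed,
                "tz_is_max": means.idxmax() == "TZ",
                "tz_separated": tz_sep,
                "control_cv": bundle["control_stats"]["ratio_cv"],
                "control_slope_p": bundle["control_stats"]["slope_p_value"],
            }
        )
    return pd.DataFrame(rows)
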