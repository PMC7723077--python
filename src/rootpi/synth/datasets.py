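"""Synthetic calibration and medium-depletion datasets."""
from __future__ import annotations

import numpy as np
import pandas as pd

from rootpi.synth.imaging import GroundTruthRecord
from rootpi.synth.sensor import IN_VITRO_SENSOR, SensorModel


def make_calibration_dataset(
    sensor: SensorModel,
    concentrations,
    n_rep: int = 8,
    noise_sd_ratio: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Injection-calibration table: replicate emission ratios per level.

    Emulates a microinjection calibration series — 6 to 8 independent
    injections per defined concentration — with Gaussian spread
    ``noise_sd_ratio`` on the ratio.  Returns a tidy table with columns
    ``{concentration_mM, ratio, replicate}`` plus the truth record.
    """
    conc = np.asarray(sorted(set(float(c) for c in concentrations)))
    if conc.size < 4:
        raise ValueError(
            f"need at least 4 distinct concentrations, got {conc.size} "
            "(fit would be under-determined)"
        )
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if not (conc.min() < sensor.kd < conc.max()):
        raise ValueError(
            "concentrations must span below and above the sensor kd "
            f"({sensor.kd} mM)"
        )
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        true_ratio = float(sensor.ratio(c))
        draws = true_ratio + rng.normal(0.0, noise_sd_ratio, size=n_rep)
        for rep, r in enumerate(draws, start=1):
            rows.append({"concentration_mM": c, "ratio": float(r), "replicate": rep})
    table = pd.DataFrame(rows)
    truth = GroundTruthRecord(
        seed=seed,
        sensor=sensor,
        params={
            "concentrations_mM": conc.tolist(),
            "n_rep": n_rep,
            "noise_sd_ratio": noise_sd_ratio,
        },
    )
    return table, truth


def make_depletion_series(
    c0: float = 0.25,
    well_volume_ml: float = 0.5,
    n_seedlings: int = 12,
    uptake_rate_nmol_per_seedling_h: float = 1.5,
    duration_h: float = 6.0,
    interval_h: float = 0.5,
    n_wells: int = 3,
    noise_sd_ratio: float = 0.0,
    sensor: SensorModel = IN_VITRO_SENSOR,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Medium Pi depletion by groups of seedlings in a multiwell plate.

    Medium Pi declines linearly at the stated per-seedling uptake rate and
    is clamped at zero (with a truth flag) once exhausted.  Each sample is
    emitted both as a concentration and as the emission ratio of the
    low-affinity in vitro converter sensor, so the downstream analysis can
    run on ratios end-to-end.  Columns: ``{time_h, well, concentration_mM,
    ratio}``.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if n_seedlings < 1:
        raise ValueError("n_seedlings must be >= 1")
    if well_volume_ml <= 0 or duration_h <= 0 or interval_h <= 0:
        raise ValueError("volumes and durations must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + interval_h / 2, interval_h)
    # nmol removed per well per hour -> mM drop per hour
    drop_per_h = uptake_rate_nmol_per_seedling_h * n_seedlings / well_volume_ml * 1e-3
    clean = c0 - drop_per_h * times
    clamped = bool(np.any(clean < 0))
    conc_true = np.clip(clean, 0.0, None)
    rows = []
    for well in range(1, n_wells + 1):
        ratios = np.asarray(sensor.ratio(conc_true), dtype=float)
        if noise_sd_ratio > 0:
            ratios = ratios + rng.normal(0.0, noise_sd_ratio, size=ratios.shape)
        for t, c, r in zip(times, conc_true, ratios):
            rows.append(
                {"time_h": float(t), "well": well,
                 "concentration_mM": float(c), "ratio": float(r)}
            )
    table = pd.DataFrame(rows)
    truth = GroundTruthRecord(
        seed=seed,
        sensor=sensor,
        params={
            "c0_mM": c0,
            "well_volume_ml": well_volume_ml,
            "n_seedlings": n_seedlings,
            "uptake_rate_nmol_per_seedling_h": uptake_rate_nmol_per_seedling_h,
            "clamped_at_zero": clamped,
        },
    )
    return table, truth
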