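"""End-to-end study orchestration: synthetic replica runs, zone
assignment, group statistics, and tidy report tables.

A run executes the stages generate -> ratiometrics -> calibrate/invert ->
statistics, writes tidy CSV tables plus a JSON summary, and is
deterministic given its seed.  The replica study places cells in the five
root-axis developmental zones with a transition-zone concentration maximum
and renders a Pi-insensitive control-sensor channel alongside.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rootpi import reference
from rootpi.calibration import assay_range, fit_isotherm, ratio_to_concentration
from rootpi.ratiometrics import (
    estimate_background,
    estimate_correction_coefficients,
    roi_emission_ratio,
)
from rootpi.stats import GroupComparison, compare_groups
from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.datasets import make_calibration_dataset
from rootpi.synth.imaging import render_frameset
from rootpi.synth.sensor import SensorModel

log = logging.getLogger("rootpi.pipeline")

__all__ = [
    "DEFAULT_ZONE_BOUNDARIES",
    "StudyConfig",
    "PipelineError",
    "ZoneProfile",
    "zone_assign",
    "run_pipeline",
]

#: Representative zone boundaries (µm from the root tip), half-open
#: intervals.  These are configuration placeholders — plausible for a
#: young primary root but not measured values — and are config-mandatory
#: for any non-synthetic analysis.
DEFAULT_ZONE_BOUNDARIES = {
    "MZ": (0.0, 200.0),
    "TZ": (200.0, 350.0),
    "EZ": (350.0, 700.0),
    "DZ": (700.0, 1500.0),
    "MR": (1500.0, math.inf),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def zone_assign(distance_from_tip: float, boundaries: dict | None = None) -> str:
    """Developmental zone for a distance from the root tip (µm).

    Half-open [lo, hi) intervals; anything beyond the last boundary is MR.
    """
    if distance_from_tip < 0:
        raise ValueError("distance from tip must be non-negative")
    boundaries = boundaries or DEFAULT_ZONE_BOUNDARIES
    edges = [b[0] for b in boundaries.values()] + [list(boundaries.values())[-1][1]]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("zone boundaries must be strictly increasing")
    for zone, (lo, hi) in boundaries.items():
        if lo <= distance_from_tip < hi:
            return zone
    return "MR"


@dataclass
class StudyConfig:
    """Resolved configuration of a synthetic replica study."""

    seed: int = 0
    sensor: dict = field(
        default_factory=lambda: {"kd": 7.4, "r_min": 1.0, "r_max": 3.0,
                                 "alpha": 0.3, "beta": 0.1}
    )
    calibration: dict | None = field(
        default_factory=lambda: {
            "concentrations": [0.0, 1.0, 3.0, 7.4, 12.0, 20.0, 30.0],
            "n_rep": 8,
            "noise_sd_ratio": 0.05,
        }
    )
    zone_means: dict = field(
        default_factory=lambda: {z: reference.ZONE_MEAN_PI_MM[z]
                                 for z in reference.AXIS_ZONES}
    )
    cell_sd_mm: float = 1.0
    n_cells_per_zone: int = 20
    n_plants: int = 5
    alpha_level: float = 0.05
    zone_boundaries: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_BOUNDARIES))
    include_control_sensor: bool = True
    scene_shape: tuple = (16, 16)
    roi_margin: int = 2

    def validate(self) -> "StudyConfig":
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must be in (0, 1)")
        if self.n_cells_per_zone < 2 or self.n_plants < 1:
            raise ValueError("need n_cells_per_zone >= 2 and n_plants >= 1")
        if self.cell_sd_mm <= 0:
            raise ValueError("cell_sd_mm must be positive")
        for zone in self.zone_means:
            if zone not in self.zone_boundaries:
                raise ValueError(f"zone {zone!r} has no boundary definition")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        cfg = cls(**data)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def resolved(self) -> dict:
        d = asdict(self)
        d["zone_boundaries"] = {
            z: [lo, "inf" if math.isinf(hi) else hi]
            for z, (lo, hi) in self.zone_boundaries.items()
        }
        return d


@dataclass
class ZoneProfile:
    """Concentration profile in 50-µm bins from the root tip."""

    table: pd.DataFrame  # bin_start_um, zone, mean_mM, sd_mM, n, censor_rate
    bin_width_um: float = 50.0


def _scene_mask(shape: tuple, margin: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[margin:-margin, margin:-margin] = True
    return mask


def _measure_cells(
    cells: list[dict],
    sensor: SensorModel,
    acq: AcquisitionModel,
    rng: np.random.Generator,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Render each cell's frameset and measure its emission ratio through
    the full background/bleedthrough correction chain."""
    rows = []
    bg = coeff = None
    for cell in cells:
        seed = int(rng.integers(2 ** 31))
        res = render_frameset(cell["c_true"], mask, sensor, acq, seed=seed)
        if bg is None:
            bg = estimate_background(res.blank)
            coeff = estimate_correction_coefficients(res.donor_only, res.acceptor_only, bg)
        meas = roi_emission_ratio(res.frames, mask, bg, coeff, intensity_floor=acq.floor)
        rows.append({**cell, "ratio": meas.ratio, "n_pixels": meas.n_pixels})
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, outdir=None) -> dict:
    """Execute a synthetic replica study; returns the report bundle.

    Bundle keys: ``calibration_fit``, ``assay_range``, ``cells`` (per-cell
    tidy table), ``control_cells``, ``zone_profile``, ``tukey`` /
    ``tukey_per_plant`` (group comparisons), ``control_stats``, ``config``.
    Writes CSV/JSON alongside a resolved-config record when ``outdir`` is
    given; identical config and seed give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"config": config.resolved()}
    acq = AcquisitionModel()

    # --- stage: calibration -------------------------------------------------
    stage = "calibration"
    try:
        if config.calibration is None:
            raise ValueError("missing calibration source in config")
        sensor = SensorModel(
            kd=config.sensor["kd"], r_min=config.sensor["r_min"],
            r_max=config.sensor["r_max"],
            alpha_true=config.sensor.get("alpha", 0.3),
            beta_true=config.sensor.get("beta", 0.1),
        )
        calib_table, _ = make_calibration_dataset(
            sensor,
            config.calibration["concentrations"],
            n_rep=config.calibration.get("n_rep", 8),
            noise_sd_ratio=config.calibration.get("noise_sd_ratio", 0.05),
            seed=int(rng.integers(2 ** 31)),
        )
        fit = fit_isotherm(calib_table)
        rng_assay = assay_range(fit)
        bundle["calibration_fit"] = fit
        bundle["assay_range"] = rng_assay
        log.info("calibration: kd = %.2f ± %.2f mM", fit.kd, fit.kd_se)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: quantify ----------------------------------------------------
    stage = "quantify"
    try:
        mask = _scene_mask(config.scene_shape, config.roi_margin)
        cells = []
        for zone, mean_c in config.zone_means.items():
            lo, hi = config.zone_boundaries[zone]
            hi = min(hi, lo + 500.0)
            for i in range(config.n_cells_per_zone):
                cells.append(
                    {
                        "zone": zone,
                        "plant": int(i % config.n_plants) + 1,
                        "cell_id": f"{zone}-{i + 1}",
                        "distance_um": float(rng.uniform(lo, hi)),
                        "c_true": float(
                            np.clip(rng.normal(mean_c, config.cell_sd_mm), 0.3, None)
                        ),
                    }
                )
        df = _measure_cells(cells, sensor, acq, rng, mask)
        ests = [ratio_to_concentration(r, fit, rng_assay) for r in df["ratio"]]
        df["concentration_mM"] = [e.concentration for e in ests]
        df["saturation"] = [e.saturation for e in ests]
        df["censor"] = [e.censor for e in ests]
        df["in_range"] = [e.in_range for e in ests]
        bundle["cells"] = df
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: control sensor ---------------------------------------------
    stage = "control"
    if config.include_control_sensor:
        try:
            null_sensor = SensorModel(
                kd=sensor.kd, r_min=sensor.r_min, r_max=sensor.r_max,
                alpha_true=sensor.alpha_true, beta_true=sensor.beta_true,
                mode="null",
            )
            ctrl = _measure_cells(cells, null_sensor, acq, rng, mask)
            from scipy.stats import linregress

            reg = linregress(ctrl["distance_um"], ctrl["ratio"])
            bundle["control_cells"] = ctrl
            bundle["control_stats"] = {
                "ratio_cv": float(ctrl["ratio"].std(ddof=1) / ctrl["ratio"].mean()),
                "slope_per_um": float(reg.slope),
                "slope_p_value": float(reg.pvalue),
            }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- stage: statistics --------------------------------------------------
    stage = "statistics"
    try:
        tukey = compare_groups(
            bundle["cells"], value="concentration_mM", group="zone",
            test="anova_tukey", alpha=config.alpha_level,
        )
        per_plant = (
            bundle["cells"].groupby(["zone", "plant"], sort=False)["concentration_mM"]
            .mean().reset_index()
        )
        tukey_plants = compare_groups(
            per_plant, value="concentration_mM", group="zone",
            test="anova_tukey", alpha=config.alpha_level,
        )
        bundle["tukey"] = tukey
        bundle["tukey_per_plant"] = tukey_plants
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: profile -----------------------------------------------------
    stage = "profile"
    try:
        df = bundle["cells"]
        width = 50.0
        bins = (df["distance_um"] // width).astype(int) * width
        prof = (
            df.assign(bin_start_um=bins)
            .groupby("bin_start_um", sort=True)
            .agg(
                zone=("zone", "first"),
                mean_mM=("concentration_mM", "mean"),
                sd_mM=("concentration_mM", "std"),
                n=("concentration_mM", "size"),
                censor_rate=("censor", lambda s: float((s != "none").mean())),
            )
            .reset_index()
        )
        bundle["zone_profile"] = ZoneProfile(table=prof, bin_width_um=width)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["cells"].to_csv(outdir / "cells.csv", index=False)
    if "control_cells" in bundle:
        bundle["control_cells"].to_csv(outdir / "control_cells.csv", index=False)
    bundle["zone_profile"].table.to_csv(outdir / "zone_profile.csv", index=False)
    fit = bundle["calibration_fit"]
    tukey: GroupComparison = bundle["tukey"]
    summary = {
        "calibration": fit.to_dict(),
        "assay_range": asdict(bundle["assay_range"]),
        "tukey_letters": tukey.letters,
        "tukey_letters_per_plant": bundle["tukey_per_plant"].letters,
        "control_stats": bundle.get("control_stats"),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "resolved_config.json").write_text(
        json.dumps(bundle["config"], indent=2, sort_keys=True)
    )
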