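"""Decomposition of cytosolic Pi dynamics into recycling, uptake, and
vacuolar sequestration, plus whole-root uptake from medium depletion.

The cyanide (CN) assay blocks Pi assimilation: the plateau rise of
cytosolic Pi under CN alone reflects metabolic recycling (Pi liberated from
organic pools), while the additional rise with external Pi present reflects
uptake.  Their difference, scaled by cytosolic volume, gives the amount of
newly acquired Pi per cell (fmol).  Vacuolar sequestration is estimated by
contrasting the uptake delta of a sequestration-defective genotype against
the wild type.  Whole-root uptake is measured independently as depletion of
Pi from the growth medium, in nmol per seedling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rootpi.calibration import CalibrationFit, concentration_from_ratio
from rootpi.units import amount_fmol

__all__ = [
    "KineticTrace",
    "PlateauResult",
    "FluxResult",
    "SequestrationResult",
    "DepletionSeries",
    "plateau_change",
    "uptake_delta",
    "amount_from_delta",
    "detectability",
    "sequestration_estimate",
    "medium_depletion_uptake",
    "percent_change_vs_control",
]

#: smallest resolvable concentration change (mM); the smallest uptake delta
#: the CN assay resolves is ~0.47 ± 0.07, so the floor sits one SE below it
DEFAULT_DETECTION_FLOOR_MM = 0.4


@dataclass
class KineticTrace:
    """Per-cell concentration time series around a treatment at t = 0 s."""

    time: np.ndarray  # s
    concentration: np.ndarray  # mM
    cell_id: str = "cell"
    zone: str = "MZ"
    genotype: str = "WT"
    treatment: str = "CN"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time.shape != self.concentration.shape:
            raise ValueError("time and concentration lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.any(self.time < 0):
            raise ValueError("trace must include pre-treatment baseline points")


@dataclass(frozen=True)
class PlateauResult:
    delta_c: float  # mM
    t_plateau: float  # s
    baseline: float  # mM
    qc_flags: frozenset = frozenset()


@dataclass(frozen=True)
class FluxResult:
    zone: str
    delta_recycling: float  # mM
    delta_combined: float  # mM
    delta_uptake: float  # mM
    t_plateau: float  # s
    uptake_amount: float  # fmol per cell
    uptake_rate: float  # fmol/s
    detectable: bool
    detection_floor: float = DEFAULT_DETECTION_FLOOR_MM
    qc_flags: frozenset = frozenset()


@dataclass(frozen=True)
class SequestrationResult:
    zone: str
    delta_wt: float  # mM
    delta_mutant: float  # mM
    sequestration_delta: float  # mM
    se: float | None = None
    qc_flags: frozenset = frozenset()


@dataclass
class DepletionSeries:
    time: np.ndarray  # h
    medium_concentration: pd.DataFrame  # columns = wells, mM
    well_volume: float  # mL
    n_seedlings: int
    cumulative_uptake: pd.DataFrame  # columns = wells, nmol/seedling
    mean_uptake: np.ndarray = field(default=None)  # nmol/seedling
    sd_uptake: np.ndarray = field(default=None)
    qc_flags: frozenset = frozenset()


def _moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    if x.size < window:
        return x.copy()
    kernel = np.ones(window) / window
    sm = np.convolve(x, kernel, mode="same")
    # repair edges (partial windows)
    half = window // 2
    for i in range(half):
        sm[i] = x[: i + half + 1].mean()
        sm[-(i + 1)] = x[-(i + half + 1):].mean()
    return sm


def plateau_change(
    trace: KineticTrace,
    plateau_tol: float = 0.05,
    top_k: int = 3,
    treatment_time: float = 0.0,
    smooth_window: int = 5,
) -> PlateauResult:
    """Plateau concentration change of a treatment-response trace.

    The post-treatment trace is smoothed with a short moving average and
    the plateau statistic is a robust maximum — the mean of the ``top_k``
    highest smoothed points (a raw maximum would be noise-biased upward).
    ``delta_c`` is that maximum minus the pre-treatment baseline mean.
    ``t_plateau`` is the first time the smoothed trace comes within
    ``plateau_tol`` (as a fraction of delta) of the plateau level, where
    the plateau level for the crossing is anchored on the tail mean of the
    smoothed trace: the top-k maximum is noise-biased upward, and anchoring
    the crossing on it would systematically delay the detected plateau
    time, whereas the tail mean is unbiased once the trace has converged.
    """
    pre = trace.time < treatment_time
    post = ~pre
    if np.count_nonzero(pre) < 3:
        raise ValueError("need at least 3 baseline points before treatment")
    if not post.any():
        raise ValueError("no post-treatment points in trace")
    t_post = trace.time[post]
    if t_post.max() - treatment_time < 15.0:
        raise ValueError("trace must span at least 15 s after treatment")
    c_pre = trace.concentration[pre]
    c_post = trace.concentration[post]
    baseline = float(c_pre.mean())
    flags = set()
    smoothed = _moving_average(c_post, smooth_window)
    k = min(top_k, smoothed.size)
    robust_max = float(np.sort(smoothed)[-k:].mean())
    delta_c = robust_max - baseline
    if delta_c <= 0:
        return PlateauResult(
            delta_c=delta_c, t_plateau=float("nan"), baseline=baseline,
            qc_flags=frozenset(flags | {"no-rise"}),
        )
    tail = float(smoothed[-min(smooth_window, smoothed.size):].mean())
    threshold = baseline + (1.0 - plateau_tol) * (tail - baseline)
    reached = np.nonzero(smoothed >= threshold)[0]
    t_plateau = float(t_post[reached[0]]) if reached.size else float("nan")
    if not reached.size:
        flags.add("plateau-not-reached")
    noise = float(c_pre.std(ddof=1)) if c_pre.size > 1 else 0.0
    if smoothed.size and robust_max - smoothed[-1] > 2.0 * max(noise, 1e-12):
        flags.add("late-decline")
    return PlateauResult(
        delta_c=delta_c, t_plateau=t_plateau, baseline=baseline,
        qc_flags=frozenset(flags),
    )


def uptake_delta(delta_combined: float, delta_recycling: float) -> tuple[float, frozenset]:
    """Uptake as the difference of the CN+Pi and CN-only plateau changes.

    Negative values (noise) are retained with a QC flag, not truncated, so
    zones with no significant uptake stay distinguishable from artifacts.
    """
    d = delta_combined - delta_recycling
    flags = frozenset({"negative-delta"}) if d < 0 else frozenset()
    return d, flags


def amount_from_delta(
    delta_c: float, volume_um3: float, assay_duration_s: float = 8.0
) -> tuple[float, float]:
    """Uptake amount (fmol) and rate (fmol/s) from a concentration change.

    ``amount = delta_c (mM) × volume (µm³) × 10⁻³``; the default assay
    duration is the 8 s needed to reach the maximum concentration change.
    """
    if delta_c < 0 or volume_um3 < 0:
        raise ValueError("delta_c and volume must be non-negative")
    amount = amount_fmol(delta_c, volume_um3)
    return amount, amount / assay_duration_s


def uptake_amount_summary(
    deltas_mm, volumes_um3, assay_duration_s: float = 8.0
) -> dict:
    """Zone-level uptake amount under both aggregation orders.

    ``mean_of_per_cell`` multiplies each cell's delta by its own volume and
    averages; ``product_of_means`` multiplies the mean delta by the mean
    volume.  The two differ whenever delta and volume co-vary, and
    published summaries do not always say which order was used, so both
    are reported.
    """
    deltas = np.asarray(deltas_mm, dtype=float)
    volumes = np.asarray(volumes_um3, dtype=float)
    if deltas.shape != volumes.shape:
        raise ValueError("deltas and volumes must align per cell")
    per_cell = deltas * volumes * 1e-3
    return {
        "mean_of_per_cell_fmol": float(per_cell.mean()),
        "sd_of_per_cell_fmol": float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0,
        "product_of_means_fmol": float(deltas.mean() * volumes.mean() * 1e-3),
        "rate_mean_fmol_per_s": float(per_cell.mean() / assay_duration_s),
        "n": int(per_cell.size),
    }


def detectability(
    amount_fmol_per_cell: float,
    volume_um3: float,
    floor_delta_mm: float = DEFAULT_DETECTION_FLOOR_MM,
) -> tuple[float, bool]:
    """Concentration change implied by an uptake amount in a given volume.

    ``implied_delta = amount / volume × 10³`` mM; the amount is detectable
    when the implied change clears the detection floor.  This reproduces
    the argument that uptake in large basal cells can hide below the
    detection limit even at apical-zone rates.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    implied = amount_fmol_per_cell / volume_um3 * 1e3
    return implied, implied >= floor_delta_mm


def decompose_fluxes(
    trace_cn: KineticTrace,
    trace_cn_pi: KineticTrace,
    volume_um3: float,
    assay_duration_s: float = 8.0,
    detection_floor: float = DEFAULT_DETECTION_FLOOR_MM,
) -> FluxResult:
    """Full per-cell decomposition from a matched pair of traces."""
    if trace_cn.zone != trace_cn_pi.zone:
        raise ValueError("traces must come from the same zone")
    p_cn = plateau_change(trace_cn)
    p_comb = plateau_change(trace_cn_pi)
    d_up, flags = uptake_delta(p_comb.delta_c, p_cn.delta_c)
    amount, rate = amount_from_delta(max(d_up, 0.0), volume_um3, assay_duration_s)
    _, detectable = detectability(amount, volume_um3, detection_floor)
    return FluxResult(
        zone=trace_cn.zone,
        delta_recycling=p_cn.delta_c,
        delta_combined=p_comb.delta_c,
        delta_uptake=d_up,
        t_plateau=p_comb.t_plateau,
        uptake_amount=amount,
        uptake_rate=rate,
        detectable=detectable,
        detection_floor=detection_floor,
        qc_flags=flags | p_cn.qc_flags | p_comb.qc_flags,
    )


def sequestration_estimate(
    delta_wt: float,
    delta_mutant: float,
    zone: str = "MZ",
    zone_mutant: str | None = None,
    se_wt: float | None = None,
    se_mutant: float | None = None,
) -> SequestrationResult:
    """Vacuolar sequestration from a wild type vs sequestration-null
    genotype contrast of uptake deltas measured in the same zone.

    In the mutant no newly acquired Pi is diverted to the vacuole, so
    ``delta_mutant - delta_wt`` estimates the sequestered concentration
    change.  Uncertainty (when per-genotype SEs are given) propagates the
    two independent errors; per-plant pairing across genotypes is not
    possible.
    """
    if zone_mutant is not None and zone_mutant != zone:
        raise ValueError(
            f"genotype contrast requires matched zones, got {zone!r} vs {zone_mutant!r}"
        )
    d = delta_mutant - delta_wt
    flags = frozenset({"negative-sequestration"}) if d < 0 else frozenset()
    se = None
    if se_wt is not None and se_mutant is not None:
        se = float(np.hypot(se_wt, se_mutant))
    return SequestrationResult(
        zone=zone, delta_wt=delta_wt, delta_mutant=delta_mutant,
        sequestration_delta=d, se=se, qc_flags=flags,
    )


def medium_depletion_uptake(
    series: pd.DataFrame,
    in_vitro_fit: CalibrationFit | None,
    well_volume_ml: float,
    n_seedlings: int,
    noise_tol_mm: float = 0.005,
) -> DepletionSeries:
    """Whole-root Pi uptake from depletion of the growth medium.

    ``series`` is a tidy table {time_h, well, ratio | concentration_mM}.
    Ratios are inverted through the in vitro calibration fit (same isotherm
    machinery as the imaging path).  Cumulative uptake per well is
    ``(C(0) - C(t)) × well_volume / n_seedlings`` in nmol/seedling, clamped
    at zero; wells whose concentration rises above the initial value beyond
    ``noise_tol_mm`` are flagged.
    """
    if well_volume_ml <= 0 or n_seedlings < 1:
        raise ValueError("well_volume and n_seedlings must be positive")
    df = series.copy()
    if "concentration_mM" not in df.columns:
        if in_vitro_fit is None:
            raise ValueError("ratio input requires an in vitro calibration fit")
        df["concentration_mM"] = concentration_from_ratio(
            df["ratio"].to_numpy(), in_vitro_fit
        )
    conc = df.pivot_table(
        index="time_h", columns="well", values="concentration_mM", sort=True
    )
    if np.any(np.diff(conc.index.to_numpy()) <= 0):
        raise ValueError("time must be strictly increasing")
    c0 = conc.iloc[0]
    if (c0 <= 0).any():
        raise ValueError("initial concentration must be positive")
    flags = set()
    if ((conc - c0) > noise_tol_mm).any().any():
        flags.add("evaporation/contamination")
    # mM × mL = µmol -> nmol: ×1000
    uptake = (c0 - conc).clip(lower=0.0) * well_volume_ml * 1000.0 / n_seedlings
    mean = uptake.mean(axis=1).to_numpy()
    sd = uptake.std(axis=1, ddof=1).to_numpy() if uptake.shape[1] > 1 else np.zeros(len(uptake))
    return DepletionSeries(
        time=conc.index.to_numpy(),
        medium_concentration=conc,
        well_volume=well_volume_ml,
        n_seedlings=n_seedlings,
        cumulative_uptake=uptake,
        mean_uptake=mean,
        sd_uptake=sd,
        qc_flags=frozenset(flags),
    )


def percent_change_vs_control(c_treated: float, c_control: float) -> float:
    """Percent change relative to control: 100·(treated - control)/control.

    Positive values indicate hyperaccumulation above the control level.
    """
    if c_control <= 0:
        raise ValueError("control concentration must be positive")
    return 100.0 * (c_treated - c_control) / c_control
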