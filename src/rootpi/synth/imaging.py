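"""Forward renderer: concentration fields -> raw three-channel framesets.

The default rendering holds the net donor emission constant across the
scene and places all concentration dependence in the sensitized component,
so the noiseless corrected ratio inside the mask equals the sensor's
response at the local analyte value exactly.  In ``physical`` sensor mode
the donor is quenched with FRET efficiency proportional to occupancy
instead (see :mod:`rootpi.synth.sensor`).

The raw FRET channel is composed as

    DA = background + alpha_true * DD_net + beta_true * AA_net + sensitized

with Poisson shot noise and Gaussian read noise per the acquisition model.
Alongside the scene, donor-only and acceptor-only reference framesets (for
bleedthrough-coefficient estimation) and a sensor-free blank (for
background estimation) are emitted, and every dataset carries a ground
truth record that regenerates bit-identically from its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rootpi.ratiometrics import RawFrameSet
from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.sensor import SensorModel

TREATMENTS = ("CN", "CN_plus_Pi")


@dataclass
class GroundTruthRecord:
    """Hidden truth carried by every synthetic dataset."""

    seed: int
    sensor: SensorModel
    pi_field: np.ndarray | None = None
    kinetic: "KineticSpec | None" = None
    volumes: dict | None = None
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KineticSpec:
    """True kinetics of the cyanide (CN) assay for one cell.

    Cytosolic Pi follows ``c_baseline + delta * (1 - exp(-t/tau))`` after
    treatment at t = 0, where delta is ``delta_recycling`` under CN alone
    and ``delta_recycling + delta_uptake * (1 - sequestration_fraction)``
    under CN plus external Pi.  ``tau`` is tied to the plateau time: the
    noiseless trace is within ``plateau_tol`` of its plateau at
    ``t_plateau_true``, drawn in [8, 10] s by the factory below.
    """

    c_baseline: float  # mM
    delta_recycling: float  # mM
    delta_uptake: float  # mM
    sequestration_fraction: float = 0.0
    t_plateau_true: float = 9.0  # s
    plateau_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.c_baseline < 0:
            raise ValueError("c_baseline must be non-negative")
        if self.delta_recycling < 0 or self.delta_uptake < 0:
            raise ValueError("deltas must be non-negative")
        if not (0 <= self.sequestration_fraction <= 1):
            raise ValueError("sequestration_fraction must be in [0, 1]")
        if not self.t_plateau_true > 0:
            raise ValueError("t_plateau_true must be positive")
        if not (0 < self.plateau_tol < 1):
            raise ValueError("plateau_tol must be in (0, 1)")

    @property
    def tau(self) -> float:
        """Exponential time constant (s) implied by the plateau time."""
        return self.t_plateau_true / math.log(1.0 / self.plateau_tol)

    def delta_for(self, treatment: str) -> float:
        if treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {treatment!r}")
        if treatment == "CN":
            return self.delta_recycling
        return self.delta_recycling + self.delta_uptake * (1.0 - self.sequestration_fraction)

    def concentration(self, t, treatment: str):
        """Noiseless cytosolic Pi (mM) at time ``t`` (s; treatment at 0)."""
        t = np.asarray(t, dtype=float)
        delta = self.delta_for(treatment)
        rise = np.where(t < 0, 0.0, delta * (1.0 - np.exp(-np.clip(t, 0, None) / self.tau)))
        return self.c_baseline + rise


def draw_kinetic_spec(
    rng: np.random.Generator,
    c_baseline: float,
    delta_recycling: float,
    delta_uptake: float,
    sequestration_fraction: float = 0.0,
) -> KineticSpec:
    """Kinetic truth with the plateau time drawn uniformly in [8, 10] s."""
    return KineticSpec(
        c_baseline=c_baseline,
        delta_recycling=delta_recycling,
        delta_uptake=delta_uptake,
        sequestration_fraction=sequestration_fraction,
        t_plateau_true=float(rng.uniform(8.0, 10.0)),
    )


@dataclass
class RenderResult:
    frames: RawFrameSet
    donor_only: RawFrameSet
    acceptor_only: RawFrameSet
    blank: RawFrameSet
    truth: GroundTruthRecord


def _expected_signals(
    pi_field: np.ndarray, mask: np.ndarray, sensor: SensorModel, acq: AcquisitionModel
) -> dict[str, np.ndarray]:
    """Noise-free expected net signals (counts) per channel component."""
    base = mask.astype(float)
    scale = acq.photon_scale
    if sensor.mode == "physical":
        e = sensor.fret_efficiency(pi_field)
        dd = scale * (1.0 - e) * base
    else:
        dd = scale * base
    ratio = sensor.ratio(pi_field)
    sens = ratio * dd
    aa = scale * base
    return {"dd": dd, "sens": sens, "aa": aa}


def render_frameset(
    pi_field,
    mask: np.ndarray,
    sensor: SensorModel,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
) -> RenderResult:
    """Render one scene plus its reference framesets and truth record.

    ``pi_field`` is a scalar (uniform concentration) or an array matching
    the mask's shape; ``mask`` (2-D or 3-D boolean) marks cytosol pixels.
    """
    acq = acq or AcquisitionModel()
    mask = np.asarray(mask, dtype=bool)
    pi_field = np.broadcast_to(np.asarray(pi_field, dtype=float), mask.shape).copy()
    if np.any(pi_field < 0):
        raise ValueError("pi_field must be non-negative")
    if pi_field.shape != mask.shape:
        raise ValueError(
            f"pi_field shape {pi_field.shape} does not match mask {mask.shape}"
        )
    rng = np.random.default_rng(seed)
    sig = _expected_signals(pi_field, mask, sensor, acq)
    da_expected = sig["sens"] + sensor.alpha_true * sig["dd"] + sensor.beta_true * sig["aa"]

    def _frameset(dd, da, aa, tag):
        return RawFrameSet(
            dd=acq.acquire(dd, "dd", rng),
            da=acq.acquire(da, "da", rng),
            aa=acq.acquire(aa, "aa", rng),
            meta={"kind": tag, "pixel_size_um": acq.pixel_size_xy, "seed": seed},
        )

    zeros = np.zeros_like(sig["dd"])
    frames = _frameset(sig["dd"], da_expected, sig["aa"], "scene")
    donor_only = _frameset(sig["dd"], sensor.alpha_true * sig["dd"], zeros, "donor_only")
    acceptor_only = _frameset(zeros, sensor.beta_true * sig["aa"], sig["aa"], "acceptor_only")
    blank = _frameset(zeros, zeros, zeros, "blank")
    truth = GroundTruthRecord(
        seed=seed,
        sensor=sensor,
        pi_field=pi_field,
        params={"mask_n_pixels": int(mask.sum()), "photon_scale": acq.photon_scale},
    )
    return RenderResult(frames, donor_only, acceptor_only, blank, truth)


@dataclass
class KineticSeriesResult:
    times: np.ndarray  # s, treatment at 0
    framesets: list  # RawFrameSet per time point
    mask: np.ndarray
    donor_only: RawFrameSet
    acceptor_only: RawFrameSet
    blank: RawFrameSet
    truth: GroundTruthRecord
    treatment: str


def simulate_kinetic_series(
    mask: np.ndarray,
    sensor: SensorModel,
    kinetic: KineticSpec,
    treatment: str,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    duration: float = 20.0,
    interval: float = 0.5,
    baseline_s: float = 3.0,
) -> KineticSeriesResult:
    """Time-lapse frameset series of the CN assay for one cell.

    Frames run from ``-baseline_s`` to ``duration`` at ``interval`` spacing
    (treatment at t = 0); each frame is rendered through the same forward
    model as :func:`render_frameset`.
    """
    acq = acq or AcquisitionModel()
    if duration <= 0 or interval <= 0:
        raise ValueError("duration and interval must be positive")
    if interval > 1.0:
        raise ValueError("frame interval must be <= 1 s")
    if duration < 20.0:
        raise ValueError("duration must be >= 20 s")
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    n = int(round((duration + baseline_s) / interval)) + 1
    times = -baseline_s + interval * np.arange(n)
    framesets = []
    zeros = np.zeros(mask.shape)
    for t in times:
        c = kinetic.concentration(t, treatment)
        sig = _expected_signals(np.broadcast_to(c, mask.shape), mask, sensor, acq)
        da = sig["sens"] + sensor.alpha_true * sig["dd"] + sensor.beta_true * sig["aa"]
        framesets.append(
            RawFrameSet(
                dd=acq.acquire(sig["dd"], "dd", rng),
                da=acq.acquire(da, "da", rng),
                aa=acq.acquire(sig["aa"], "aa", rng),
                meta={"kind": "scene", "time_s": float(t), "seed": seed},
            )
        )
    ref_sig = _expected_signals(
        np.broadcast_to(kinetic.c_baseline, mask.shape), mask, sensor, acq
    )
    donor_only = RawFrameSet(
        dd=acq.acquire(ref_sig["dd"], "dd", rng),
        da=acq.acquire(sensor.alpha_true * ref_sig["dd"], "da", rng),
        aa=acq.acquire(zeros, "aa", rng),
        meta={"kind": "donor_only"},
    )
    acceptor_only = RawFrameSet(
        dd=acq.acquire(zeros, "dd", rng),
        da=acq.acquire(sensor.beta_true * ref_sig["aa"], "da", rng),
        aa=acq.acquire(ref_sig["aa"], "aa", rng),
        meta={"kind": "acceptor_only"},
    )
    blank = RawFrameSet(
        dd=acq.acquire(zeros, "dd", rng),
        da=acq.acquire(zeros, "da", rng),
        aa=acq.acquire(zeros, "aa", rng),
        meta={"kind": "blank"},
    )
    truth = GroundTruthRecord(
        seed=seed,
        sensor=sensor,
        kinetic=kinetic,
        params={"treatment": treatment, "interval_s": interval, "duration_s": duration},
    )
    return KineticSeriesResult(
        times=times,
        framesets=framesets,
        mask=mask,
        donor_only=donor_only,
        acceptor_only=acceptor_only,
        blank=blank,
        truth=truth,
        treatment=treatment,
    )
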