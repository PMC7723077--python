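"""Sensitized-emission ratiometrics for three-channel FRET framesets.

A frameset holds the three acquisition channels of a sensitized-emission
FRET measurement:

* ``dd`` — donor excitation / donor emission (eCFP-class donor)
* ``da`` — donor excitation / acceptor emission (raw FRET channel)
* ``aa`` — acceptor excitation / acceptor emission (cpVenus-class acceptor)

The raw FRET channel contains, besides the FRET-specific (sensitized)
signal, donor spectral bleedthrough (a fraction ``alpha`` of the net donor
signal) and direct acceptor cross-excitation (a fraction ``beta`` of the net
acceptor signal).  After mean-background subtraction the sensitized signal
is ``F_sens = DA_net - alpha*DD_net - beta*AA_net`` and the reported
emission ratio of a region of interest is the intensity-weighted ratio
``sum(F_sens) / sum(DD_net)`` over pixels with adequate donor signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("dd", "da", "aa")

__all__ = [
    "RawFrameSet",
    "BackgroundEstimate",
    "CorrectionCoefficients",
    "RatioMeasurement",
    "estimate_background",
    "estimate_correction_coefficients",
    "sensitized_emission",
    "roi_emission_ratio",
]


@dataclass
class RawFrameSet:
    """Co-registered DD/DA/AA channel images with acquisition metadata."""

    dd: np.ndarray
    da: np.ndarray
    aa: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dd = np.asarray(self.dd, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        self.aa = np.asarray(self.aa, dtype=float)
        if not (self.dd.shape == self.da.shape == self.aa.shape):
            raise ValueError(
                "channel shape mismatch: "
                f"dd {self.dd.shape}, da {self.da.shape}, aa {self.aa.shape}"
            )
        for name in CHANNELS:
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"channel {name!r} contains negative counts")

    @property
    def shape(self) -> tuple:
        return self.dd.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel mean background in counts."""

    dd: float
    da: float
    aa: float
    source: str = "reference_frameset"
    n_pixels: int = 0

    def __post_init__(self) -> None:
        for name in CHANNELS:
            if getattr(self, name) < 0:
                raise ValueError(f"background {name!r} must be non-negative")

    def channel(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Donor bleedthrough (alpha) and acceptor cross-excitation (beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not (0 <= self.beta < 1):
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")


@dataclass(frozen=True)
class RatioMeasurement:
    """Sensitized/donor emission ratio over a region of interest."""

    ratio: float | None
    n_pixels: int
    dispersion: float
    qc_flags: frozenset = frozenset()

    @property
    def ok(self) -> bool:
        return self.ratio is not None and "low-signal" not in self.qc_flags


def _clamped_net(image: np.ndarray, background: float) -> tuple[np.ndarray, int]:
    net = np.asarray(image, dtype=float) - background
    clamped = int(np.count_nonzero(net < 0))
    return np.clip(net, 0.0, None), clamped


def subtract_background(
    frames: RawFrameSet, bg: BackgroundEstimate
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Mean-background subtraction, clamped at zero.

    Returns the net images per channel and the count of clamped (negative)
    pixels per channel as a QC record.
    """
    nets, clamped = {}, {}
    for name in CHANNELS:
        nets[name], clamped[name] = _clamped_net(
            frames.channel(name), bg.channel(name)
        )
    return nets, clamped


def estimate_background(
    reference: RawFrameSet, region: np.ndarray | None = None
) -> BackgroundEstimate:
    """Per-channel mean background from a sensor-free reference.

    ``reference`` is a frameset of an untransformed (sensor-free) specimen,
    or any frameset with ``region`` restricting to a blank area.
    """
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != reference.shape:
            raise ValueError("region shape does not match frameset")
        if not region.any():
            raise ValueError("empty background region")
    n = int(region.sum()) if region is not None else int(np.prod(reference.shape))
    if n == 0:
        raise ValueError("empty background reference")
    means = {}
    for name in CHANNELS:
        img = reference.channel(name)
        means[name] = float(img[region].mean() if region is not None else img.mean())
    source = "blank_region" if region is not None else "reference_frameset"
    return BackgroundEstimate(source=source, n_pixels=n, **means)


def _origin_slope(
    x: np.ndarray, y: np.ndarray, floor: float, trim: float = 0.01
) -> float:
    """Least-squares slope through the origin of y vs x over above-floor
    pixels, after trimming the extreme per-pixel ratios (hot-pixel guard)."""
    keep = x > floor
    if np.count_nonzero(keep) < 10:
        raise ValueError(
            f"insufficient above-floor pixels ({int(keep.sum())}) "
            "for coefficient estimation"
        )
    x, y = x[keep], y[keep]
    if trim > 0 and x.size >= 100:
        r = y / x
        lo, hi = np.quantile(r, [trim, 1 - trim])
        inner = (r >= lo) & (r <= hi)
        x, y = x[inner], y[inner]
    return float(np.sum(x * y) / np.sum(x * x))


def estimate_correction_coefficients(
    donor_only: RawFrameSet,
    acceptor_only: RawFrameSet,
    background: BackgroundEstimate,
    intensity_floor: float = 0.0,
) -> CorrectionCoefficients:
    """Estimate alpha and beta from single-fluorophore reference framesets.

    alpha is the through-origin slope of net DA vs net DD over donor-only
    pixels; beta likewise for net DA vs net AA over acceptor-only pixels.
    """
    d_net, _ = subtract_background(donor_only, background)
    a_net, _ = subtract_background(acceptor_only, background)
    alpha = _origin_slope(d_net["dd"].ravel(), d_net["da"].ravel(), intensity_floor)
    beta = _origin_slope(a_net["aa"].ravel(), a_net["da"].ravel(), intensity_floor)
    return CorrectionCoefficients(alpha=alpha, beta=beta)


def sensitized_emission(
    frames: RawFrameSet,
    bg: BackgroundEstimate,
    coeff: CorrectionCoefficients,
) -> tuple[np.ndarray, int]:
    """FRET-specific acceptor emission image.

    ``F_sens = (DA - bg_DA) - alpha*(DD - bg_DD) - beta*(AA - bg_AA)``,
    clamped at zero.  Returns the image and the number of clamped pixels.
    """
    nets, _ = subtract_background(frames, bg)
    f_sens = nets["da"] - coeff.alpha * nets["dd"] - coeff.beta * nets["aa"]
    clamped = int(np.count_nonzero(f_sens < 0))
    return np.clip(f_sens, 0.0, None), clamped


def roi_emission_ratio(
    frames: RawFrameSet,
    roi: np.ndarray,
    bg: BackgroundEstimate,
    coeff: CorrectionCoefficients,
    intensity_floor: float = 0.0,
) -> RatioMeasurement:
    """Intensity-weighted emission ratio of a region of interest.

    Pixels whose net donor signal falls below ``intensity_floor`` are
    excluded.  The ratio is sum(F_sens)/sum(DD_net) over the kept pixels
    (robust to shot noise at low counts); the dispersion reported is the SD
    of the per-pixel ratios.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != frames.shape:
        raise ValueError("ROI shape does not match frameset")
    if not roi.any():
        raise ValueError("empty ROI")
    nets, _ = subtract_background(frames, bg)
    f_sens, n_clamped = sensitized_emission(frames, bg, coeff)
    dd_net = nets["dd"]
    keep = roi & (dd_net > intensity_floor)
    flags = set()
    if n_clamped > 0:
        flags.add("clamped")
    n_kept = int(keep.sum())
    if n_kept == 0:
        return RatioMeasurement(
            ratio=None, n_pixels=0, dispersion=float("nan"),
            qc_flags=frozenset(flags | {"low-signal"}),
        )
    sens_sum = float(f_sens[keep].sum())
    dd_sum = float(dd_net[keep].sum())
    per_pixel = f_sens[keep] / dd_net[keep]
    dispersion = float(per_pixel.std(ddof=1)) if n_kept > 1 else 0.0
    return RatioMeasurement(
        ratio=sens_sum / dd_sum,
        n_pixels=n_kept,
        dispersion=dispersion,
        qc_flags=frozenset(flags),
    )
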