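"""Isotherm calibration: ratio <-> absolute Pi concentration.

The sensor's corrected emission ratio follows a single-site binding
isotherm,

    R(C) = r_min + (r_max - r_min) * C / (kd + C),

fitted here by (weighted) nonlinear least squares with grid-seeded starting
values.  Inversion,

    C(R) = kd * (R - r_min) / (r_max - R),

is exact on (r_min, r_max).  Because the ligand-binding response is
nonlinear, concentration estimates are gated to a fractional-saturation
window (defaults 20%-80%); out-of-range estimates are retained but
censor-flagged rather than discarded, so downstream summaries can report
censoring rates.  Concentration uncertainty carries the fitted Kd's
relative error under a uniform-relative-error assumption; the full
delta-method value is attached as a diagnostic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "AssayRange",
    "ConcentrationEstimate",
    "IsothermFitError",
    "fit_isotherm",
    "ratio_to_concentration",
    "concentration_from_ratio",
    "saturation_to_concentration",
    "kd_relative_error",
    "assay_range",
]


class IsothermFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # mM
    ratio_mean: float
    ratio_sd: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class CalibrationFit:
    r_min: float
    r_max: float
    kd: float  # mM
    kd_se: float  # mM
    covariance: np.ndarray  # order (r_min, r_max, kd)
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.r_max > self.r_min:
            raise ValueError("r_max must exceed r_min")
        if not self.kd > 0:
            raise ValueError("kd must be positive")

    @property
    def kd_rel_err(self) -> float:
        return self.kd_se / self.kd

    def ratio(self, c):
        """Forward isotherm ratio at concentration ``c`` (mM)."""
        c = np.asarray(c, dtype=float)
        return self.r_min + (self.r_max - self.r_min) * c / (self.kd + c)

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "kd_mM": self.kd,
            "kd_se_mM": self.kd_se,
            "kd_rel_err": self.kd_rel_err,
            "covariance": np.asarray(self.covariance).tolist(),
            "diagnostics": self.fit_diagnostics,
        }


@dataclass(frozen=True)
class AssayRange:
    s_lo: float
    s_hi: float
    c_lo: float  # mM
    c_hi: float  # mM
    source: str = "isotherm"

    def __post_init__(self) -> None:
        if not (0 < self.s_lo < self.s_hi < 1):
            raise ValueError("need 0 < s_lo < s_hi < 1")
        if not self.c_lo < self.c_hi:
            raise ValueError("need c_lo < c_hi")


@dataclass(frozen=True)
class ConcentrationEstimate:
    concentration: float  # mM
    saturation: float
    rel_error: float
    in_range: bool
    censor: str = "none"  # none | below | above
    rel_error_delta: float | None = None  # delta-method diagnostic


def _isotherm(c, r_min, r_max, kd):
    return r_min + (r_max - r_min) * c / (kd + c)


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, int]:
    """Normalize input to (conc, ratio, sigma, n_obs).

    Raw tables ({concentration_mM, ratio, ...}) are fitted point-wise and
    unweighted; aggregated tables ({concentration_mM, ratio_mean, ratio_sd,
    n}) are weighted by the standard error of each mean.
    """
    if isinstance(points, pd.DataFrame):
        if "ratio" in points.columns:
            c = points["concentration_mM"].to_numpy(dtype=float)
            r = points["ratio"].to_numpy(dtype=float)
            return c, r, None, len(points)
        c = points["concentration_mM"].to_numpy(dtype=float)
        r = points["ratio_mean"].to_numpy(dtype=float)
        sd = points["ratio_sd"].to_numpy(dtype=float)
        n = points["n"].to_numpy(dtype=float)
        sigma = np.where(sd > 0, sd / np.sqrt(n), np.nan)
        if np.isnan(sigma).any():
            sigma = None
        return c, r, sigma, len(points)
    pts = list(points)
    c = np.array([p.concentration for p in pts])
    r = np.array([p.ratio_mean for p in pts])
    sd = np.array([p.ratio_sd for p in pts])
    n = np.array([p.n for p in pts], dtype=float)
    sigma = sd / np.sqrt(n) if np.all(sd > 0) else None
    return c, r, sigma, len(pts)


def _grid_start(c: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    """Seed (r_min, r_max, kd) by profiling kd over a log-spaced grid;
    at fixed kd the isotherm is linear in (r_min, r_max)."""
    c_pos = c[c > 0]
    center = np.median(c_pos) if c_pos.size else 1.0
    best = None
    for kd in np.geomspace(center * 1e-2, center * 1e2, 41):
        s = c / (kd + c)
        design = np.column_stack([1.0 - s, s])
        coef, res, *_ = np.linalg.lstsq(design, r, rcond=None)
        sse = float(((design @ coef - r) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, coef[0], coef[1], kd)
    _, r_min0, r_max0, kd0 = best
    if r_max0 <= r_min0:
        r_min0, r_max0 = float(r.min()), float(r.max())
    return r_min0, r_max0, kd0


def fit_isotherm(points) -> CalibrationFit:
    """Fit R(C) = r_min + (r_max - r_min)·C/(kd + C) to calibration data.

    ``points`` is a tidy raw table ({concentration_mM, ratio, replicate}),
    an aggregated table ({concentration_mM, ratio_mean, ratio_sd, n}), or a
    sequence of :class:`CalibrationPoint`.  Weighted least squares when
    replicate SDs are available; Kd ± SE comes from the parameter
    covariance.
    """
    c, r, sigma, n_obs = _as_points(points)
    if np.unique(c).size < 4:
        raise ValueError(
            f"need at least 4 distinct concentrations, got {np.unique(c).size}"
        )
    if np.ptp(r) == 0:
        raise ValueError("ratios not all equal: zero dynamic range, cannot fit")
    p0 = _grid_start(c, r)
    try:
        popt, pcov = curve_fit(
            _isotherm,
            c,
            r,
            p0=p0,
            sigma=sigma,
            absolute_sigma=False,
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        raise IsothermFitError(
            f"isotherm fit failed to converge: {exc}; starts {p0}, "
            f"{n_obs} observations"
        ) from exc
    r_min, r_max, kd = (float(v) for v in popt)
    resid = r - _isotherm(c, *popt)
    diagnostics = {
        "n_obs": n_obs,
        "rss": float((resid ** 2).sum()),
        "residual_sd": float(resid.std(ddof=min(3, n_obs - 1))),
        "start": tuple(float(v) for v in p0),
        "weighted": sigma is not None,
    }
    if kd <= 1e-8 or not np.isfinite(pcov).all():
        diagnostics["warning"] = "kd at parameter bound"
    kd_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return CalibrationFit(
        r_min=r_min, r_max=r_max, kd=kd, kd_se=kd_se,
        covariance=np.asarray(pcov), fit_diagnostics=diagnostics,
    )


def saturation_to_concentration(s: float, kd: float) -> float:
    """Concentration (mM) at fractional saturation ``s``: C = kd·s/(1-s)."""
    if not 0 < s < 1:
        raise ValueError(f"saturation must be in (0, 1), got {s}")
    if kd <= 0:
        raise ValueError("kd must be positive")
    return kd * s / (1.0 - s)


def kd_relative_error(fit_or_kd, se: float | None = None) -> float:
    """Relative error of Kd in percent: 100·kd_se/kd.

    Accepts a :class:`CalibrationFit` or an explicit ``(kd, se)`` pair.
    Display contexts round to the nearest integer percent; the returned
    value is unrounded.
    """
    if isinstance(fit_or_kd, CalibrationFit):
        kd, se = fit_or_kd.kd, fit_or_kd.kd_se
    else:
        kd = float(fit_or_kd)
        if se is None:
            raise ValueError("se required when kd given as a number")
    if kd <= 0:
        raise ValueError("kd must be positive")
    return 100.0 * se / kd


def assay_range(
    fit: CalibrationFit,
    s_lo: float = 0.2,
    s_hi: float = 0.8,
    c_lo: float | None = None,
    c_hi: float | None = None,
) -> AssayRange:
    """Concentration window of adequate sensor response.

    Defaults compute c_lo/c_hi from the fitted isotherm at 20% and 80%
    saturation; explicit ``c_lo``/``c_hi`` overrides are stored verbatim
    with ``source="config"``.
    """
    if s_lo >= s_hi:
        raise ValueError(f"s_lo ({s_lo}) must be < s_hi ({s_hi})")
    if c_lo is not None and c_hi is not None:
        return AssayRange(s_lo=s_lo, s_hi=s_hi, c_lo=c_lo, c_hi=c_hi, source="config")
    return AssayRange(
        s_lo=s_lo,
        s_hi=s_hi,
        c_lo=saturation_to_concentration(s_lo, fit.kd),
        c_hi=saturation_to_concentration(s_hi, fit.kd),
        source="isotherm",
    )


def concentration_from_ratio(ratios, fit: CalibrationFit) -> np.ndarray:
    """Vectorized nominal inversion C = kd·(R - r_min)/(r_max - R).

    Ratios at or beyond the asymptotes map to 0 / +inf; use
    :func:`ratio_to_concentration` for censored scalar estimates.
    """
    r = np.asarray(ratios, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = fit.kd * (r - fit.r_min) / (fit.r_max - r)
    c = np.where(r <= fit.r_min, 0.0, c)
    c = np.where(r >= fit.r_max, np.inf, c)
    return c


def _delta_method_rel_error(c: float, fit: CalibrationFit) -> float | None:
    """Relative SE of C(R) propagating the full parameter covariance."""
    if c <= 0:
        return None
    r = float(fit.ratio(c))
    denom = fit.r_max - r
    if denom <= 0:
        return None
    g = np.array(
        [
            -fit.kd / denom,  # d/dr_min
            -fit.kd * (r - fit.r_min) / denom ** 2,  # d/dr_max
            (r - fit.r_min) / denom,  # d/dkd
        ]
    )
    cov = np.asarray(fit.covariance)
    # covariance order is (r_min, r_max, kd)
    var = float(g @ cov @ g)
    if var < 0 or not np.isfinite(var):
        return None
    return float(np.sqrt(var) / c)


def ratio_to_concentration(
    ratio: float,
    fit: CalibrationFit,
    rng: AssayRange | None = None,
) -> ConcentrationEstimate:
    """Invert one emission ratio to a censored concentration estimate.

    All pathological ratios map to censored estimates rather than errors:
    R <= r_min gives C = 0 (censor "below"); R >= r_max is replaced by the
    upper assay bound (censor "above").  Estimates inside (r_min, r_max)
    but outside [c_lo, c_hi] are returned with the violated bound flagged.
    """
    rng = rng or assay_range(fit)
    rel = fit.kd_rel_err
    if ratio <= fit.r_min:
        return ConcentrationEstimate(
            concentration=0.0, saturation=0.0, rel_error=rel,
            in_range=False, censor="below",
        )
    if ratio >= fit.r_max:
        c = rng.c_hi
        return ConcentrationEstimate(
            concentration=c, saturation=c / (fit.kd + c), rel_error=rel,
            in_range=False, censor="above",
        )
    c = float(fit.kd * (ratio - fit.r_min) / (fit.r_max - ratio))
    in_range = rng.c_lo <= c <= rng.c_hi
    censor = "none"
    if c < rng.c_lo:
        censor = "below"
    elif c > rng.c_hi:
        censor = "above"
    return ConcentrationEstimate(
        concentration=c,
        saturation=c / (fit.kd + c),
        rel_error=rel,
        in_range=in_range,
        censor=censor,
        rel_error_delta=_delta_method_rel_error(c, fit),
    )
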