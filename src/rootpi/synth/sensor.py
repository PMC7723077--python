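"""FRET phosphate-sensor response models.

The responsive sensor follows a single-site binding isotherm: at analyte
concentration C the corrected emission ratio is

    R(C) = r_min + (r_max - r_min) * C / (kd + C)

Three behaviours are generable:

* ``responsive`` — the ratio is exactly isotherm-shaped (the default
  rendering holds net donor emission constant and puts all concentration
  dependence into the sensitized component).
* ``null`` — a control sensor whose ratio is invariant to the analyte
  (renders at the midpoint ratio regardless of concentration).
* ``physical`` — donor quenching with FRET efficiency proportional to
  fractional occupancy, so the rendered ratio is hyperbolic in occupancy
  rather than exactly isotherm-shaped; used to probe robustness of
  isotherm fitting to mechanistic deviations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("responsive", "null", "physical")


@dataclass(frozen=True)
class SensorModel:
    kd: float
    r_min: float
    r_max: float
    alpha_true: float = 0.3
    beta_true: float = 0.1
    mode: str = "responsive"
    #: physical mode only: FRET efficiency at full occupancy
    e_max: float = 0.4

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if not self.r_min > 0:
            raise ValueError(f"r_min must be positive, got {self.r_min}")
        if not self.r_max > self.r_min:
            raise ValueError(
                f"r_max ({self.r_max}) must exceed r_min ({self.r_min})"
            )
        for name in ("alpha_true", "beta_true"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "physical" and not (0 < self.e_max < 1):
            raise ValueError(f"e_max must be in (0, 1), got {self.e_max}")

    def occupancy(self, c):
        """Fractional saturation S = C/(kd + C)."""
        c = np.asarray(c, dtype=float)
        return c / (self.kd + c)

    def ratio(self, c):
        """Noiseless corrected emission ratio at concentration ``c`` (mM)."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        if self.mode == "null":
            return np.full_like(c, 0.5 * (self.r_min + self.r_max))
        s = self.occupancy(c)
        if self.mode == "responsive":
            return self.r_min + (self.r_max - self.r_min) * s
        # physical: ratio = (r_min + k*E) / (1 - E), E = e_max * S;
        # k chosen so the ratio still spans [r_min, r_max]
        e = self.e_max * s
        k = (self.r_max * (1.0 - self.e_max) - self.r_min) / self.e_max
        return (self.r_min + k * e) / (1.0 - e)

    def fret_efficiency(self, c):
        """Donor-quenching FRET efficiency (physical mode)."""
        return self.e_max * self.occupancy(c)


def build_sensor_model(
    kd: float,
    r_min: float,
    r_max: float,
    alpha: float = 0.3,
    beta: float = 0.1,
    mode: str = "responsive",
    e_max: float = 0.4,
) -> SensorModel:
    """Validated sensor model; see :class:`SensorModel`."""
    return SensorModel(
        kd=kd, r_min=r_min, r_max=r_max,
        alpha_true=alpha, beta_true=beta, mode=mode, e_max=e_max,
    )


#: in vivo sensor defaults: Kd 7.4 mM, a ~3x ratio dynamic range
DEFAULT_SENSOR = SensorModel(kd=7.4, r_min=1.0, r_max=3.0)

#: low-affinity in vitro converter used for medium (depletion) assays;
#: synthetic stand-in parameters for an "-80u"-class sensor (Kd 80 µM)
IN_VITRO_SENSOR = SensorModel(kd=0.08, r_min=0.5, r_max=2.5)
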