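"""Camera/optics acquisition model: voxel geometry and the noise model.

Noise is the standard camera model — Poisson on the photon signal
(including background) plus additive Gaussian read noise.  Setting
``shot_noise=False`` together with ``read_noise_sd=0`` gives an exact,
deterministic render used by closed-loop identities in tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from rootpi.units import DEFAULT_VOXEL_UM3

#: pixel size giving a 0.06 µm³ voxel at the default 0.5 µm z-step
DEFAULT_PIXEL_XY = math.sqrt(DEFAULT_VOXEL_UM3 / 0.5)


@dataclass(frozen=True)
class AcquisitionModel:
    pixel_size_xy: float = DEFAULT_PIXEL_XY  # µm
    z_step: float = 0.5  # µm
    background_mean: tuple[float, float, float] = (100.0, 100.0, 100.0)  # dd, da, aa
    read_noise_sd: float = 5.0  # counts
    photon_scale: float = 5000.0  # counts per unit fluorophore signal
    intensity_floor: float | None = None  # counts; default 3x read noise
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_xy > 0:
            raise ValueError(f"pixel_size_xy must be positive, got {self.pixel_size_xy}")
        if not self.z_step > 0:
            raise ValueError(f"z_step must be positive, got {self.z_step}")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if any(b < 0 for b in self.background_mean):
            raise ValueError("background_mean must be non-negative")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_xy ** 2 * self.z_step

    @property
    def floor(self) -> float:
        if self.intensity_floor is not None:
            return self.intensity_floor
        return 3.0 * self.read_noise_sd

    @property
    def noiseless(self) -> bool:
        return (not self.shot_noise) and self.read_noise_sd == 0

    def background(self, channel: str) -> float:
        return dict(zip(("dd", "da", "aa"), self.background_mean))[channel]

    def acquire(self, signal: np.ndarray, channel: str, rng: np.random.Generator) -> np.ndarray:
        """Turn an expected photon-signal image into recorded counts."""
        expected = np.asarray(signal, dtype=float) + self.background(channel)
        if np.any(expected < 0):
            raise ValueError("expected signal must be non-negative")
        counts = rng.poisson(expected).astype(float) if self.shot_noise else expected.copy()
        if self.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, self.read_noise_sd, size=counts.shape)
        return np.clip(counts, 0.0, None)
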