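"""Synthetic cell geometries with volumes matching measured magnitudes."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rootpi.reference import CYTOSOL_VOLUME_UM3, ZONES
from rootpi.synth.acquisition import AcquisitionModel


@dataclass
class CellGeometry:
    zone: str
    mask: np.ndarray  # 3-D boolean, cytosol voxels
    target_volume: float  # µm³
    distance_from_tip: float  # µm
    voxel_volume: float  # µm³

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        realized = self.volume_um3
        if self.target_volume > 0 and abs(realized - self.target_volume) > 0.1 * self.target_volume:
            raise ValueError(
                f"realized volume {realized:.1f} µm³ deviates more than 10% "
                f"from target {self.target_volume:.1f} µm³"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_um3(self) -> float:
        return self.n_voxels * self.voxel_volume


def _cuboid_mask(n_voxels: int) -> np.ndarray:
    """Smallest near-cubic 3-D mask containing exactly ``n_voxels`` True
    voxels, filled in raster order (shape is irrelevant to volumetry)."""
    side = max(1, round(n_voxels ** (1 / 3)))
    nz = max(2, side)
    nyx = int(np.ceil(np.sqrt(n_voxels / nz)))
    shape = (nz, nyx + 1, nyx + 1)
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    flat[:n_voxels] = True
    return flat.reshape(shape)


def make_cell_geometry(
    zone: str,
    condition: str = "replete",
    acq: AcquisitionModel | None = None,
    rng: np.random.Generator | None = None,
    distance_from_tip: float = 0.0,
) -> CellGeometry:
    """Draw a cytosol geometry whose volume matches the reference
    magnitude for ``(zone, condition)``.

    The target volume is drawn from the reference mean ± sd (truncated at
    20% of the mean) and realized exactly as a voxel count.
    """
    acq = acq or AcquisitionModel()
    rng = rng or np.random.default_rng(0)
    if (zone, condition) not in CYTOSOL_VOLUME_UM3:
        raise ValueError(f"unknown zone/condition {(zone, condition)!r}")
    mean, sd = CYTOSOL_VOLUME_UM3[(zone, condition)]
    target = float(np.clip(rng.normal(mean, sd), 0.2 * mean, None))
    n_vox = max(1, round(target / acq.voxel_volume_um3))
    mask = _cuboid_mask(n_vox)
    return CellGeometry(
        zone=zone,
        mask=mask,
        target_volume=n_vox * acq.voxel_volume_um3,
        distance_from_tip=distance_from_tip,
        voxel_volume=acq.voxel_volume_um3,
    )
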