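"""Cytosolic volume estimation from confocal Z-stacks.

Volumes are estimated by thresholding each optical slice (Otsu by
default), counting above-threshold voxels inside a region of interest, and
multiplying by the voxel volume (default 0.06 µm³ from a 0.5 µm z-step).
Also holds the microinjection geometry utilities: spherical droplet volume
from its diameter, and injection fold-excess over the target cell volume.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from rootpi.units import DEFAULT_VOXEL_UM3, UM3_PER_PL, um3_to_pl

__all__ = [
    "ZStack",
    "CellMask3D",
    "VolumeEstimate",
    "InjectionRecord",
    "threshold_stack",
    "voxel_volume",
    "droplet_volume",
    "fold_excess",
]


@dataclass
class ZStack:
    """3-D intensity image (z, y, x) with its voxel volume in µm³."""

    intensity: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_UM3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("Z-stack intensity must be 3-D (z, y, x)")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")


@dataclass
class CellMask3D:
    mask: np.ndarray
    roi_id: str = "cell"
    method: str = "per_slice_otsu"
    per_slice_thresholds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")


@dataclass(frozen=True)
class VolumeEstimate:
    n_voxels: int
    volume_um3: float
    volume_pl: float
    roi_id: str = "cell"
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class InjectionRecord:
    droplet_diameter: float  # µm
    injection_volume: float  # pL
    target_cell_volume: float  # pL
    fold_excess: float


def threshold_stack(
    stack: ZStack,
    method: str = "per_slice_otsu",
    roi: np.ndarray | None = None,
    fixed_threshold: float | None = None,
    roi_id: str = "cell",
) -> CellMask3D:
    """Per-slice thresholding of a Z-stack, restricted to a region.

    ``per_slice_otsu`` computes an Otsu threshold per optical slice;
    ``fixed`` applies ``fixed_threshold`` everywhere.  Slices with no
    contrast yield an empty contribution with a warning, not an error.
    ``roi`` may be 2-D (applied to every slice) or 3-D.
    """
    img = stack.intensity
    if img.size == 0:
        raise ValueError("empty Z-stack")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.ndim == 2:
            roi = np.broadcast_to(roi, img.shape)
        if roi.shape != img.shape:
            raise ValueError("ROI shape does not match stack")
    mask = np.zeros(img.shape, dtype=bool)
    thresholds: list[float] = []
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        mask = img > fixed_threshold
        thresholds = [float(fixed_threshold)] * img.shape[0]
    elif method == "per_slice_otsu":
        for z in range(img.shape[0]):
            sl = img[z]
            if np.ptp(sl) == 0:
                thresholds.append(float("nan"))
                continue
            try:
                t = float(threshold_otsu(sl))
            except ValueError:
                thresholds.append(float("nan"))
                continue
            # bimodality guard: Otsu on a single-class (noise-only) slice
            # splits the noise in half; require the two classes to separate
            # by more than their internal spread before accepting the slice
            above, below = sl[sl > t], sl[sl <= t]
            spread = max(above.std(), below.std(), 1e-12)
            if above.mean() - below.mean() < 4.0 * spread:
                thresholds.append(float("nan"))
                continue
            thresholds.append(t)
            mask[z] = sl > t
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    if roi is not None:
        mask &= roi
    if not mask.any():
        warnings.warn(f"thresholding produced an empty mask for {roi_id!r}")
    return CellMask3D(
        mask=mask, roi_id=roi_id, method=method, per_slice_thresholds=thresholds
    )


def voxel_volume(mask: CellMask3D | np.ndarray, voxel_size: float) -> VolumeEstimate:
    """Count true voxels and convert to µm³ and pL."""
    if not voxel_size > 0:
        raise ValueError("voxel_size must be positive")
    arr = mask.mask if isinstance(mask, CellMask3D) else np.asarray(mask, dtype=bool)
    roi_id = mask.roi_id if isinstance(mask, CellMask3D) else "cell"
    n = int(arr.sum())
    flags = frozenset({"empty-mask"}) if n == 0 else frozenset()
    vol = n * voxel_size
    return VolumeEstimate(
        n_voxels=n,
        volume_um3=vol,
        volume_pl=um3_to_pl(vol),
        roi_id=roi_id,
        flags=flags,
    )


def droplet_volume(diameter_um: float) -> float:
    """Volume (pL) of a spherical droplet of the given diameter (µm)."""
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * diameter_um ** 3 / 6.0 / UM3_PER_PL


def fold_excess(injection_volume_pl: float, cell_volume_pl: float) -> float:
    """Injected volume as a multiple of the target cell's cytosolic volume."""
    if cell_volume_pl <= 0:
        raise ValueError("cell volume must be positive")
    ratio = injection_volume_pl / cell_volume_pl
    return float(f"{ratio:.3g}")


def injection_record(diameter_um: float, cell_volume_pl: float) -> InjectionRecord:
    vol = droplet_volume(diameter_um)
    return InjectionRecord(
        droplet_diameter=diameter_um,
        injection_volume=vol,
        target_cell_volume=cell_volume_pl,
        fold_excess=fold_excess(vol, cell_volume_pl),
    )
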