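"""Intensity Z-stack phantoms with analytically known volumes."""
from __future__ import annotations

import math

import numpy as np

from rootpi.reference import CYTOSOL_VOLUME_UM3
from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.geometry import _cuboid_mask
from rootpi.volumetry import ZStack

KINDS = ("cube", "sphere", "table1_cell")


def make_zstack_phantom(
    kind: str,
    acq: AcquisitionModel | None = None,
    *,
    size_voxels: int = 10,
    radius_um: float = 5.0,
    zone: str = "MZ",
    condition: str = "replete",
    image_shape: tuple[int, int, int] | None = None,
    foreground: float = 1000.0,
    seed: int = 0,
) -> tuple[ZStack, float]:
    """Return an intensity Z-stack realizing a phantom and its true volume.

    Kinds: ``cube`` (``size_voxels`` per side), ``sphere`` (``radius_um``;
    true volume is the analytic 4πr³/3), ``table1_cell`` (a cell-sized blob
    whose voxel count matches the reference cytosolic volume for
    ``(zone, condition)``).  Foreground voxels carry ``foreground`` expected
    signal over background; noise follows the acquisition model.
    """
    acq = acq or AcquisitionModel()
    vv = acq.voxel_volume_um3
    if kind == "cube":
        n = int(size_voxels)
        if n < 1:
            raise ValueError("cube size must be >= 1 voxel")
        mask = np.ones((n, n, n), dtype=bool)
        true_volume = n ** 3 * vv
    elif kind == "sphere":
        if radius_um <= 0:
            raise ValueError("sphere radius must be positive")
        nz = int(math.ceil(radius_um / acq.z_step)) + 2
        nxy = int(math.ceil(radius_um / acq.pixel_size_xy)) + 2
        z = (np.arange(2 * nz + 1) - nz) * acq.z_step
        y = (np.arange(2 * nxy + 1) - nxy) * acq.pixel_size_xy
        zz, yy, xx = np.meshgrid(z, y, y, indexing="ij")
        mask = zz ** 2 + yy ** 2 + xx ** 2 <= radius_um ** 2
        true_volume = 4.0 / 3.0 * math.pi * radius_um ** 3
    elif kind == "table1_cell":
        target, _sd = CYTOSOL_VOLUME_UM3[(zone, condition)]
        n_vox = max(1, round(target / vv))
        mask = _cuboid_mask(n_vox)
        true_volume = n_vox * vv
    else:
        raise ValueError(f"unknown phantom kind {kind!r}; expected one of {KINDS}")

    # background margin so every occupied slice carries both classes
    mask = np.pad(mask, 2)

    if image_shape is not None:
        if any(m > s for m, s in zip(mask.shape, image_shape)):
            raise ValueError(
                f"phantom of shape {mask.shape} exceeds requested image "
                f"shape {tuple(image_shape)}"
            )
        padded = np.zeros(image_shape, dtype=bool)
        padded[tuple(slice(0, m) for m in mask.shape)] = mask
        mask = padded

    rng = np.random.default_rng(seed)
    intensity = acq.acquire(foreground * mask.astype(float), "aa", rng)
    stack = ZStack(
        intensity=intensity,
        voxel_size=vv,
        meta={"kind": kind, "seed": seed, "z_step_um": acq.z_step},
    )
    return stack, float(true_volume)
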