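"""File I/O: multi-page TIFF framesets and Z-stacks with JSON sidecars,
labeled mask TIFFs, and run-length ROI tables."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from rootpi.ratiometrics import CHANNELS, RawFrameSet
from rootpi.volumetry import ZStack


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_frameset(frames: RawFrameSet, path) -> Path:
    """Write the three channels as one multi-page TIFF plus a JSON sidecar
    recording channel order and metadata."""
    path = Path(path)
    stack = np.stack([frames.channel(c) for c in CHANNELS]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {"channels": list(CHANNELS), "meta": _jsonable(frames.meta)}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_frameset(path) -> RawFrameSet:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    order = meta.get("channels", list(CHANNELS))
    data = {name: stack[i] for i, name in enumerate(order)}
    return RawFrameSet(meta=meta.get("meta", {}), **data)


def save_zstack(stack: ZStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.intensity.astype(np.float32), photometric="minisblack")
    meta = {"voxel_size_um3": stack.voxel_size, "meta": _jsonable(stack.meta)}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_zstack(path) -> ZStack:
    path = Path(path)
    intensity = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return ZStack(
        intensity=intensity,
        voxel_size=meta.get("voxel_size_um3", 0.06),
        meta=meta.get("meta", {}),
    )


def save_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean or labeled mask as a TIFF (uint16 labels)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16), photometric="minisblack")
    return path


def load_mask(path, label: int | None = None) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return arr == label if label is not None else arr > 0


def mask_to_runlength(mask: np.ndarray) -> pd.DataFrame:
    """Run-length encode a 2-D/3-D boolean mask along the fastest axis.

    Columns: {z, y, x_start, x_end} with half-open x ranges; z is 0 for
    2-D masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        mask = mask[None]
    rows = []
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            line = mask[z, y]
            edges = np.flatnonzero(np.diff(np.concatenate(([0], line.view(np.int8), [0]))))
            for start, end in zip(edges[::2], edges[1::2]):
                rows.append({"z": z, "y": y, "x_start": int(start), "x_end": int(end)})
    return pd.DataFrame(rows, columns=["z", "y", "x_start", "x_end"])


def runlength_to_mask(table: pd.DataFrame, shape: tuple) -> np.ndarray:
    squeeze = len(shape) == 2
    full = (1, *shape) if squeeze else shape
    mask = np.zeros(full, dtype=bool)
    for _, row in table.iterrows():
        mask[int(row["z"]), int(row["y"]), int(row["x_start"]):int(row["x_end"])] = True
    return mask[0] if squeeze else mask


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
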