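"""Reading and writing the package's on-disk formats.

Movies and λ-stacks are multi-page TIFF (frame-major; band-major for spectral
stacks, with band centers in a JSON sidecar next to the TIFF).  Masks are
single-page labeled TIFF.  Tables (trajectories, spots, diffusion estimates)
are CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, RegionMask

PathLike = Union[str, Path]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_stack(path: PathLike, stack: ImageStack) -> Path:
    """Write an ImageStack as TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    meta = {
        "axes": stack.axes,
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "band_centers_nm": (
            None
            if stack.band_centers_nm is None
            else [float(v) for v in stack.band_centers_nm]
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: PathLike) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (sidecar optional)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bands = meta.get("band_centers_nm")
        return ImageStack(
            data=data,
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=meta.get("frame_interval_s"),
            band_centers_nm=None if bands is None else np.asarray(bands, float),
            axes=meta["axes"],
        )
    axes = "YX" if data.ndim == 2 else "TYX"
    return ImageStack(data=data, pixel_size_um=1.0, axes=axes)


def write_mask(path: PathLike, mask: RegionMask) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask.labels, dtype=np.uint8))
    return path


def read_mask(path: PathLike) -> RegionMask:
    return RegionMask(labels=tifffile.imread(Path(path)))


def write_tracks(path: PathLike, tracks: pd.DataFrame) -> Path:
    """Write a trajectory table (`track_id,frame,x_um,y_um` [+ extras])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks.to_csv(path, index=False)
    return path


def read_tracks(path: PathLike) -> pd.DataFrame:
    tracks = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    return tracks
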