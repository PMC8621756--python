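"""Core containers shared across the analysis modules.

The package works on three kinds of pixel data:

* time-lapse movies (``axes="TYX"``) from TIRF-style single-particle imaging,
* single images (``axes="YX"`` or ``"CYX"`` for multi-channel), and
* spectral λ-stacks (``axes="BYX"``), one plane per emission band.

All physical calibration travels with the pixels: μm per pixel, seconds per
frame, and nm band centers for spectral data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

# Region labels used by every mask in the package.
BACKGROUND = 0
PM = 1  # plasma-membrane band
INTERIOR = 2  # cell interior; endosome label in spectral masks
CYTOPLASM = 3

REGION_NAMES = {
    BACKGROUND: "background",
    PM: "pm",
    INTERIOR: "interior",
    CYTOPLASM: "cytoplasm",
}


@dataclass
class ImageStack:
    """Pixel array plus physical calibration.

    Parameters
    ----------
    data:
        Array of shape (H, W), (T, H, W), (C, H, W) or (B, H, W) depending
        on ``axes``.
    pixel_size_um:
        Lateral calibration, μm per pixel.
    frame_interval_s:
        Time between frames for movies; ``None`` for single images.
    band_centers_nm:
        Emission band centers for λ-stacks (axis ``B``); ``None`` otherwise.
    axes:
        One of ``"YX"``, ``"TYX"``, ``"CYX"``, ``"BYX"``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: Optional[float] = None
    band_centers_nm: Optional[np.ndarray] = None
    axes: str = "TYX"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.axes not in ("YX", "TYX", "CYX", "BYX"):
            raise ValueError(f"unknown axes spec {self.axes!r}")
        expected_ndim = 2 if self.axes == "YX" else 3
        if self.data.ndim != expected_ndim:
            raise ValueError(
                f"axes {self.axes!r} require {expected_ndim}-D data, "
                f"got shape {self.data.shape}"
            )
        if self.band_centers_nm is not None:
            self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=float)
            if self.axes == "BYX" and len(self.band_centers_nm) != self.data.shape[0]:
                raise ValueError("band_centers_nm length must match band axis")

    @property
    def n_frames(self) -> int:
        return 1 if self.axes == "YX" else self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]


@dataclass
class RegionMask:
    """Labeled pixel partition of an image.

    Labels follow the module-level constants: 0 background, 1 PM band,
    2 interior/endosome, 3 cytoplasm.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")

    def region(self, label: int) -> np.ndarray:
        """Boolean pixel mask of one label."""
        return self.labels == label

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise description.

    ``kind`` is one of ``"poisson"`` (shot noise on signal+background),
    ``"gaussian"`` (additive read noise of standard deviation ``sd``) or
    ``"none"``.  Poisson and Gaussian can be combined by ``gaussian_sd > 0``
    with ``kind="poisson"``.
    """

    kind: str = "poisson"
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(image, dtype=float)
        if self.kind == "poisson":
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if self.kind == "gaussian" or self.gaussian_sd > 0:
            sd = self.gaussian_sd
            if sd > 0:
                out = out + rng.normal(0.0, sd, size=out.shape)
        return out


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for a named pipeline stage.

    Streams are derived from the master seed and the stage name, so adding a
    stage never perturbs the randomness of existing ones.
    """
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )
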