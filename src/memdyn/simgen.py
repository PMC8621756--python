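"""Synthetic fluorescence-microscopy data with known ground truth.

Three generators cover the three kinds of data the analysis modules consume:

* :func:`simulate_tirf_movie` — a TIRF-style movie of diffraction-limited
  spots undergoing free 2D Brownian motion, one or more diffusion
  populations, with the true trajectories returned alongside the pixels.
* :func:`simulate_cell_image` — a single cell image with a bright
  plasma-membrane (PM) band and planted endosomal puncta on a cytoplasmic
  background, plus the ground-truth region mask and punctum table.
* :func:`simulate_lambda_stack` — a spectral (λ) stack in which each pixel's
  emission spectrum is a convex mixture of an "ordered" and a "disordered"
  basis spectrum, the mixing fraction set per region.

All generators are deterministic given their spec's ``seed``: the same spec
reproduces the same pixels and tables bit for bit.

The Brownian step standard deviation σ (per axis, per frame) relates to the
2D diffusion coefficient by D = σ² / (2·Δt); the analysis modules estimate D
back from the rendered movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BACKGROUND,
    CYTOPLASM,
    INTERIOR,
    PM,
    ImageStack,
    NoiseModel,
    RegionMask,
)

__all__ = [
    "Population",
    "TirfSimSpec",
    "CellGeometry",
    "CellImageSimSpec",
    "SpectralSimSpec",
    "simulate_tirf_movie",
    "simulate_cell_image",
    "simulate_lambda_stack",
    "gaussian_basis",
    "default_band_centers",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


# ---------------------------------------------------------------------------
# TIRF-style single-particle movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One diffusive sub-population.

    ``fraction`` of particles take per-axis Gaussian steps of standard
    deviation ``step_sigma_um`` each frame, i.e. D = σ²/(2Δt).
    """

    fraction: float
    step_sigma_um: float


@dataclass(frozen=True)
class TirfSimSpec:
    """Parameters of a simulated single-particle movie.

    Defaults emulate typical variable-angle TIRF acquisition of a
    membrane-bound GFP fusion: 0.1 μm pixels, 50 ms frames, a
    diffraction-limited PSF (σ = 0.125 μm), and a single slow population
    whose step σ of 13.96 nm corresponds to D ≈ 1.95×10⁻³ μm²/s.
    """

    n_particles: int = 300
    n_frames: int = 50
    frame_interval_s: float = 0.05
    pixel_size_um: float = 0.1
    populations: tuple[Population, ...] = (Population(1.0, 0.01396),)
    psf_sigma_um: float = 0.125
    photon_scale: float = 2000.0
    background_level: float = 10.0
    noise_model: NoiseModel = NoiseModel("poisson")
    field_size_px: tuple[int, int] = (256, 256)  # (height, width)
    min_separation_um: float = 1.0
    localization_jitter_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        fractions = sum(p.fraction for p in self.populations)
        if abs(fractions - 1.0) > 1e-9:
            raise ValueError(
                f"population fractions must sum to 1 (got {fractions!r})"
            )
        for p in self.populations:
            if p.step_sigma_um < 0:
                raise ValueError("step sigma must be >= 0")
            # RMS 2D step is σ√2; anything beyond half the field makes the
            # motion unresolvable in a movie of this size.
            rms_step = p.step_sigma_um * np.sqrt(2.0)
            half_field = 0.5 * min(self.field_size_px) * self.pixel_size_um
            if rms_step > half_field:
                raise ValueError(
                    f"RMS per-frame step {rms_step:.3g} μm exceeds half the "
                    f"field ({half_field:.3g} μm)"
                )
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be > 0")
        if self.localization_jitter_um < 0:
            raise ValueError("localization_jitter_um must be >= 0")

    @property
    def diffusion_coefficients(self) -> tuple[float, ...]:
        """True D of each population, μm²/s (D = σ²/(2Δt))."""
        return tuple(
            p.step_sigma_um**2 / (2.0 * self.frame_interval_s)
            for p in self.populations
        )


def _population_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Apportion n particles to populations by largest remainder."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:remainder]:
        counts[int(i)] += 1
    return counts


def _place_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_separation: float,
) -> np.ndarray:
    """Rejection-sample n points with a pairwise minimum separation."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {n} points with separation "
                f"{min_separation} after {attempts} attempts"
            )
        candidate = rng.uniform(low, high)
        attempts += 1
        if points and min_separation > 0:
            d2 = np.sum((np.asarray(points) - candidate) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        points.append(candidate)
    return np.asarray(points)


def _render_spots(
    frame: np.ndarray,
    xy_px: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> None:
    """Add 2D Gaussian spots (integrated intensity = amplitude) in place."""
    h, w = frame.shape
    half = max(3, int(np.ceil(4 * sigma_px)))
    peak = amplitudes / (2.0 * np.pi * sigma_px**2)
    for (x, y), a in zip(xy_px, peak):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        frame[y0:y1, x0:x1] += a * g


def simulate_tirf_movie(
    spec: TirfSimSpec,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a Brownian-spot movie and return it with the true trajectories.

    Returns
    -------
    movie:
        ``ImageStack`` of shape (n_frames, H, W) with Poisson (and optional
        Gaussian) noise applied.
    truth:
        Trajectory table with columns ``track_id, frame, x_um, y_um,
        population``; positions are the noise-free Brownian ground truth.
        Trajectories are truncated at the frame before they first leave the
        field of view.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    px = spec.pixel_size_um
    field_um = np.array([w * px, h * px])  # (x, y) extent

    margin = 4 * spec.psf_sigma_um
    starts = _place_points(
        rng,
        spec.n_particles,
        low=np.array([margin, margin]),
        high=field_um - margin,
        min_separation=spec.min_separation_um,
    )

    counts = _population_counts(
        [p.fraction for p in spec.populations], spec.n_particles
    )
    pop_of_particle = np.repeat(np.arange(len(counts)), counts)

    sigmas = np.array([p.step_sigma_um for p in spec.populations])
    steps = rng.normal(
        0.0, 1.0, size=(spec.n_particles, spec.n_frames - 1, 2)
    ) * sigmas[pop_of_particle][:, None, None]
    positions = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(steps, axis=1)],
        axis=1,
    )  # (n_particles, n_frames, 2) in μm, (x, y)

    # Truncate each trajectory at the frame before it first exits the field.
    inside = (
        (positions[..., 0] >= 0)
        & (positions[..., 0] < field_um[0])
        & (positions[..., 1] >= 0)
        & (positions[..., 1] < field_um[1])
    )
    first_out = np.where(
        inside.all(axis=1), spec.n_frames, np.argmin(inside, axis=1)
    )

    if spec.localization_jitter_um > 0:
        rendered = positions + rng.normal(
            0.0, spec.localization_jitter_um, size=positions.shape
        )
    else:
        rendered = positions

    sigma_px = spec.psf_sigma_um / px
    frames = np.empty((spec.n_frames, h, w), dtype=float)
    amplitudes = np.full(spec.n_particles, spec.photon_scale, dtype=float)
    for t in range(spec.n_frames):
        frame = np.full((h, w), float(spec.background_level))
        alive = first_out > t
        if alive.any():
            _render_spots(frame, rendered[alive, t] / px, amplitudes[alive], sigma_px)
        frames[t] = spec.noise_model.apply(frame, rng)

    rows = []
    for i in range(spec.n_particles):
        n_t = int(first_out[i])
        rows.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "frame": np.arange(n_t),
                    "x_um": positions[i, :n_t, 0],
                    "y_um": positions[i, :n_t, 1],
                    "population": pop_of_particle[i],
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)

    movie = ImageStack(
        data=frames,
        pixel_size_um=px,
        frame_interval_s=spec.frame_interval_s,
        axes="TYX",
    )
    return movie, truth


# ---------------------------------------------------------------------------
# Cell images with a PM band and endosomal puncta
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """Disk-shaped cell: PM band is the annulus [radius − thickness, radius]."""

    radius_px: float = 60.0
    pm_thickness_px: float = 4.0
    center_px: Optional[tuple[float, float]] = None  # (y, x); default = field center

    def __post_init__(self) -> None:
        if self.radius_px <= self.pm_thickness_px:
            raise ValueError("radius must exceed PM thickness")


@dataclass(frozen=True)
class CellImageSimSpec:
    """Parameters of a simulated endocytosis-assay cell image.

    Defaults mimic a confocal FM4-64 field: a bright PM ring (mean 200 a.u.),
    a dim cytoplasmic interior (30 a.u.), and ``n_puncta`` diffraction-limited
    endosomal puncta of peak amplitude ``puncta_intensity`` planted strictly
    inside the cell, each at least 2·puncta_sigma from the PM band.
    """

    field_size_px: tuple[int, int] = (160, 160)
    geometry: CellGeometry = CellGeometry()
    n_puncta: int = 46
    puncta_intensity: float = 200.0  # peak amplitude above local background
    puncta_sigma_um: float = 0.125
    pixel_size_um: float = 0.1
    pm_mean_intensity: float = 200.0
    interior_mean_intensity: float = 30.0
    background_mean_intensity: float = 5.0
    min_puncta_separation_um: float = 0.75  # 6 × PSF σ by default
    noise_model: NoiseModel = NoiseModel("poisson")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "puncta_intensity",
            "pm_mean_intensity",
            "interior_mean_intensity",
            "background_mean_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.puncta_sigma_um <= 0:
            raise ValueError("puncta_sigma_um must be > 0")


def _cell_mask(spec: CellImageSimSpec) -> tuple[RegionMask, np.ndarray]:
    h, w = spec.field_size_px
    geo = spec.geometry
    cy, cx = geo.center_px if geo.center_px is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[r <= geo.radius_px] = PM
    labels[r <= geo.radius_px - geo.pm_thickness_px] = INTERIOR
    return RegionMask(labels), r


def simulate_cell_image(
    spec: CellImageSimSpec,
) -> tuple[ImageStack, RegionMask, pd.DataFrame]:
    """Render one cell image; return pixels, region mask, and punctum table.

    The punctum table has columns ``x_um, y_um, amplitude`` (true sub-pixel
    centers).  Placement is rejection-sampled to keep every punctum strictly
    inside the interior label, ≥ 2·puncta_sigma from the PM band, and at
    pairwise distance ≥ ``min_puncta_separation_um``; failure to place all
    puncta within the attempt budget raises ``RuntimeError``.
    """
    rng = np.random.default_rng(spec.seed)
    mask, _ = _cell_mask(spec)
    h, w = spec.field_size_px
    px = spec.pixel_size_um
    geo = spec.geometry
    cy, cx = geo.center_px if geo.center_px is not None else ((h - 1) / 2, (w - 1) / 2)

    sigma_px = spec.puncta_sigma_um / px
    # Puncta must stay 2σ clear of the PM band's inner edge.
    r_max_px = geo.radius_px - geo.pm_thickness_px - 2 * sigma_px
    if spec.n_puncta > 0 and r_max_px <= 0:
        raise RuntimeError("cell interior too small to hold any punctum")

    centers: list[np.ndarray] = []
    attempts = 0
    min_sep_px = spec.min_puncta_separation_um / px
    while len(centers) < spec.n_puncta:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {spec.n_puncta} puncta without overlap "
                f"after {attempts} attempts"
            )
        attempts += 1
        # Uniform over the allowed disk.
        rr = r_max_px * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cand = np.array([cx + rr * np.cos(th), cy + rr * np.sin(th)])  # (x, y)
        if centers and min_sep_px > 0:
            d2 = np.sum((np.asarray(centers) - cand) ** 2, axis=1)
            if d2.min() < min_sep_px**2:
                continue
        centers.append(cand)
    centers_px = np.asarray(centers).reshape(-1, 2)

    image = np.full((h, w), float(spec.background_mean_intensity))
    image[mask.region(PM)] = spec.pm_mean_intensity
    image[mask.region(INTERIOR)] = spec.interior_mean_intensity
    # Peak-amplitude parameterization: integrated intensity = a·2πσ².
    integrated = spec.puncta_intensity * 2 * np.pi * sigma_px**2
    _render_spots(
        image,
        centers_px,
        np.full(len(centers_px), integrated),
        sigma_px,
    )
    image = spec.noise_model.apply(image, rng)

    table = pd.DataFrame(
        {
            "x_um": centers_px[:, 0] * px,
            "y_um": centers_px[:, 1] * px,
            "amplitude": spec.puncta_intensity,
        }
        if len(centers_px)
        else {"x_um": [], "y_um": [], "amplitude": []}
    )
    stack = ImageStack(data=image, pixel_size_um=px, axes="YX")
    return stack, mask, table


# ---------------------------------------------------------------------------
# Spectral λ-stacks
# ---------------------------------------------------------------------------


def default_band_centers() -> np.ndarray:
    """23 emission bands at 495 + 9k nm, k = 0..22 (495–693 nm)."""
    return 495.0 + 9.0 * np.arange(23)


def gaussian_basis(
    band_centers_nm: np.ndarray, peak_nm: float, width_nm: float, amplitude: float = 200.0
) -> np.ndarray:
    """Unimodal Gaussian emission basis sampled at the band centers."""
    band_centers_nm = np.asarray(band_centers_nm, float)
    return amplitude * np.exp(
        -((band_centers_nm - peak_nm) ** 2) / (2 * width_nm**2)
    )


def _check_unimodal(spectrum: np.ndarray, name: str) -> int:
    """Validate non-negativity and a single interior maximum; return argmax."""
    s = np.asarray(spectrum, float)
    if (s < 0).any():
        raise ValueError(f"{name} must be non-negative")
    k = int(np.argmax(s))
    if k in (0, len(s) - 1):
        raise ValueError(f"{name} must peak strictly inside the band range")
    d = np.diff(s)
    # Unimodal: non-decreasing up to the max, non-increasing after.
    if (d[:k] < -1e-12 * s.max()).any() or (d[k:] > 1e-12 * s.max()).any():
        raise ValueError(f"{name} must be unimodal")
    return k


@dataclass(frozen=True)
class SpectralSimSpec:
    """Parameters of a simulated x-y-λ acquisition.

    Each pixel spectrum in region ``r`` is
    ``f_r · ordered_basis + (1 − f_r) · disordered_basis + noise`` with
    ``f_r = region_ordered_fraction[r]``.  Defaults emulate an
    environment-sensitive membrane dye: an ordered-phase basis peaking at
    560 nm and a red-shifted disordered-phase basis peaking at 630 nm,
    sampled on 23 bands from 495 nm at 9 nm spacing.  The default regions
    are a PM annulus (ordered fraction 0.8) and planted endosome disks
    (0.4) on a faint cytoplasm (0.3).
    """

    field_size_px: tuple[int, int] = (160, 160)
    geometry: CellGeometry = CellGeometry()
    n_endosomes: int = 12
    endosome_radius_px: float = 3.0
    band_centers_nm: tuple[float, ...] = tuple(default_band_centers())
    ordered_basis: Optional[tuple[float, ...]] = None  # default Gaussian @560 nm
    disordered_basis: Optional[tuple[float, ...]] = None  # default Gaussian @630 nm
    region_ordered_fraction: Mapping[int, float] = field(
        default_factory=lambda: {PM: 0.8, INTERIOR: 0.4, CYTOPLASM: 0.3}
    )
    cytoplasm_amplitude_scale: float = 0.15
    pixel_size_um: float = 0.1
    noise_model: NoiseModel = NoiseModel("poisson")
    seed: int = 0

    def __post_init__(self) -> None:
        bands = np.asarray(self.band_centers_nm, float)
        if len(bands) < 3 or (np.diff(bands) <= 0).any():
            raise ValueError("band_centers_nm must be strictly ascending (>= 3 bands)")
        for r, f in self.region_ordered_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"ordered fraction for region {r} outside [0, 1]")
        ob, db = self.bases()
        k_o = _check_unimodal(ob, "ordered_basis")
        k_d = _check_unimodal(db, "disordered_basis")
        if bands[k_o] >= bands[k_d]:
            raise ValueError(
                "ordered basis must peak at a shorter wavelength than the "
                "disordered basis"
            )

    def bases(self) -> tuple[np.ndarray, np.ndarray]:
        bands = np.asarray(self.band_centers_nm, float)
        ob = (
            gaussian_basis(bands, 560.0, 35.0)
            if self.ordered_basis is None
            else np.asarray(self.ordered_basis, float)
        )
        db = (
            gaussian_basis(bands, 630.0, 45.0)
            if self.disordered_basis is None
            else np.asarray(self.disordered_basis, float)
        )
        if len(ob) != len(bands) or len(db) != len(bands):
            raise ValueError("basis spectra must match band_centers_nm length")
        return ob, db


def simulate_lambda_stack(
    spec: SpectralSimSpec,
) -> tuple[ImageStack, RegionMask]:
    """Render a λ-stack (bands × H × W) and its region mask.

    Regions: 1 = PM annulus, 2 = endosome disks, 3 = cytoplasm,
    0 = extracellular background (dark).  Endosome centers are
    rejection-sampled inside the cell, clear of the PM band and of each
    other.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    geo = spec.geometry
    cy, cx = geo.center_px if geo.center_px is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)

    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[r <= geo.radius_px] = PM
    labels[r <= geo.radius_px - geo.pm_thickness_px] = CYTOPLASM

    # Plant endosome disks inside the cytoplasm.
    r_max = geo.radius_px - geo.pm_thickness_px - spec.endosome_radius_px - 1
    centers: list[np.ndarray] = []
    attempts = 0
    min_sep = 2 * spec.endosome_radius_px + 2
    while len(centers) < spec.n_endosomes:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError("could not place endosomes without overlap")
        attempts += 1
        rr = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cand = np.array([cy + rr * np.sin(th), cx + rr * np.cos(th)])  # (y, x)
        if centers:
            d2 = np.sum((np.asarray(centers) - cand) ** 2, axis=1)
            if d2.min() < min_sep**2:
                continue
        centers.append(cand)
    for ecy, ecx in centers:
        d = np.hypot(yy - ecy, xx - ecx)
        labels[d <= spec.endosome_radius_px] = INTERIOR

    ob, db = spec.bases()
    n_bands = len(ob)
    stack = np.zeros((n_bands, h, w), dtype=float)
    for region, f in spec.region_ordered_fraction.items():
        sel = labels == region
        if not sel.any():
            continue
        spectrum = f * ob + (1 - f) * db
        if region == CYTOPLASM:
            spectrum = spectrum * spec.cytoplasm_amplitude_scale
        stack[:, sel] = spectrum[:, None]
    stack = spec.noise_model.apply(stack, rng)

    image = ImageStack(
        data=stack,
        pixel_size_um=spec.pixel_size_um,
        band_centers_nm=np.asarray(spec.band_centers_nm, float),
        axes="BYX",
    )
    return image, RegionMask(labels)
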