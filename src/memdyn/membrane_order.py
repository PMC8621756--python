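"""Spectral and ratiometric membrane-order analysis.

Environment-sensitive membrane dyes emit at shorter wavelengths in ordered
(raft-like) lipid phases and red-shift in disordered phases.  Three readouts
quantify this:

* **Emission profiles** from λ-stacks: per-region mean spectra with a
  sub-band peak wavelength; a blue-shift of the peak indicates a more
  ordered membrane.
* **RGM** (red-to-green ratio of membrane fluorescence): RGM = I_660/I_550,
  the ratio of the red-window (620–750 nm) to green-window (500–580 nm)
  region mean.  Lower RGM means higher order.
* **GP** (generalized polarization):
  GP = (I_ord − G·I_dis)/(I_ord + G·I_dis) per pixel, with the instrument
  G-factor correcting relative channel sensitivity.  Higher GP means higher
  order; region-wise peak GP values come from single-Gaussian fits to the
  pixel-GP histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ImageStack, RegionMask
from .spt_dynamics import PeakFit, fit_peak_histogram

__all__ = [
    "SpectralProfile",
    "GPImage",
    "RGMResult",
    "GPHistogramFit",
    "GREEN_WINDOW_NM",
    "RED_WINDOW_NM",
    "band_integrate",
    "extract_spectral_profiles",
    "compute_rgm",
    "compute_gp_image",
    "fit_region_gp_peaks",
    "calibrate_g_factor",
]

# Acquisition windows for the two ratiometric channels (nm).
GREEN_WINDOW_NM = (500.0, 580.0)
RED_WINDOW_NM = (620.0, 750.0)


# ---------------------------------------------------------------------------
# λ-stack profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralProfile:
    """Mean emission spectrum of one region, normalized to its maximum."""

    region: int
    band_centers_nm: np.ndarray
    mean_intensity: np.ndarray  # raw per-band ROI mean, a.u.
    normalized: np.ndarray  # mean_intensity / max
    peak_wavelength_nm: float  # sub-band, by quadratic interpolation


def _quadratic_peak(bands: np.ndarray, y: np.ndarray) -> float:
    """Vertex of the parabola through the 3 samples around the discrete max.

    Falls back to the band center itself when the maximum sits on an edge
    or the three points are degenerate; the result is clamped to the band
    range.
    """
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return float(bands[k])
    x3, y3 = bands[k - 1 : k + 2], y[k - 1 : k + 2]
    a, b, _ = np.polyfit(x3, y3, 2)
    if a >= 0:  # not a maximum
        return float(bands[k])
    peak = -b / (2 * a)
    return float(np.clip(peak, bands[0], bands[-1]))


def extract_spectral_profiles(
    stack: ImageStack,
    mask: RegionMask,
    n_rois: int = 20,
    roi_shape_px: tuple[int, int] = (3, 3),
    regions: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> list[SpectralProfile]:
    """Per-region emission profiles from randomly placed rectangular ROIs.

    For each region label, ``n_rois`` equal-size rectangles lying entirely
    inside that label are sampled with a seeded RNG; the per-band mean over
    all ROI pixels is the region's profile.  Raises ``ValueError`` when a
    region cannot fit a single ROI.
    """
    if stack.axes != "BYX" or stack.band_centers_nm is None:
        raise ValueError("expected a BYX λ-stack with band centers")
    if stack.frame_shape != mask.shape:
        raise ValueError("mask shape must match stack frames")
    bands = stack.band_centers_nm
    data = np.asarray(stack.data, float)
    rh, rw = roi_shape_px
    rng = np.random.default_rng(seed)

    if regions is None:
        regions = [r for r in mask.present_labels() if r != 0]

    from scipy import ndimage

    profiles = []
    for region in regions:
        sel = mask.region(region)
        # Valid anchors: top-left corners whose whole rectangle is inside.
        # minimum_filter output at center c covers [c - k//2, c + (k-1)//2],
        # so the anchor of a fully-inside window at center c is c - k//2.
        minfilt = ndimage.minimum_filter(
            sel.astype(np.uint8), size=(rh, rw), mode="constant", cval=0
        )
        centers = np.argwhere(minfilt > 0)
        anchors = centers - np.array([rh // 2, rw // 2])
        h, w = sel.shape
        in_bounds = (
            (anchors[:, 0] >= 0)
            & (anchors[:, 1] >= 0)
            & (anchors[:, 0] + rh <= h)
            & (anchors[:, 1] + rw <= w)
        )
        anchors = anchors[in_bounds]
        if len(anchors) == 0:
            raise ValueError(
                f"region {region} too small to fit a {rh}x{rw} ROI"
            )
        take = min(n_rois, len(anchors))
        idx = rng.choice(len(anchors), size=take, replace=len(anchors) < n_rois)
        pix = np.zeros(sel.shape, dtype=bool)
        for ay, ax in anchors[idx]:
            pix[ay : ay + rh, ax : ax + rw] = True
        pix &= sel
        spectrum = data[:, pix].mean(axis=1)
        peak = _quadratic_peak(bands, spectrum)
        norm = spectrum / spectrum.max() if spectrum.max() > 0 else spectrum
        profiles.append(
            SpectralProfile(
                region=int(region),
                band_centers_nm=bands.copy(),
                mean_intensity=spectrum,
                normalized=norm,
                peak_wavelength_nm=peak,
            )
        )
    return profiles


def band_integrate(
    stack: ImageStack, window_nm: tuple[float, float]
) -> np.ndarray:
    """Weighted mean of a λ-stack over an emission window.

    Each band nominally covers ± half the band spacing around its center;
    bands overlapping the window boundary contribute pro-rata by overlap
    fraction.  Returns a 2D image.
    """
    if stack.axes != "BYX" or stack.band_centers_nm is None:
        raise ValueError("expected a BYX λ-stack with band centers")
    bands = stack.band_centers_nm
    spacing = np.diff(bands)
    half = np.empty(len(bands))
    half[:-1] = spacing / 2
    half[-1] = spacing[-1] / 2
    lo_edge = bands - np.concatenate([[spacing[0] / 2], spacing / 2])[: len(bands)]
    hi_edge = bands + half
    wlo, whi = window_nm
    overlap = np.clip(np.minimum(hi_edge, whi) - np.maximum(lo_edge, wlo), 0, None)
    widths = hi_edge - lo_edge
    weights = overlap / widths
    if weights.sum() == 0:
        raise ValueError(f"no band overlaps window {window_nm}")
    data = np.asarray(stack.data, float)
    return np.tensordot(weights, data, axes=(0, 0)) / weights.sum()


# ---------------------------------------------------------------------------
# RGM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RGMResult:
    """Red-to-green ratio of one region: RGM = I_660 / I_550."""

    region: int
    rgm: float
    i_660: float  # red-window region mean (620–750 nm acquisition)
    i_550: float  # green-window region mean (500–580 nm acquisition)


def compute_rgm(
    green: np.ndarray,
    red: np.ndarray,
    mask: RegionMask,
    region: int,
) -> RGMResult:
    """RGM of one region from the two window-integrated channel images.

    ``RGM = mean(red over region) / mean(green over region)``.  The green
    region mean must be positive.
    """
    green = np.asarray(green, float)
    red = np.asarray(red, float)
    if green.shape != red.shape or green.shape != mask.shape:
        raise ValueError("channel images and mask must share a shape")
    sel = mask.region(region)
    if not sel.any():
        raise ValueError(f"region {region} is empty")
    i550 = float(green[sel].mean())
    i660 = float(red[sel].mean())
    if i550 <= 0:
        raise ValueError("green-channel region mean must be positive")
    return RGMResult(region=int(region), rgm=i660 / i550, i_660=i660, i_550=i550)


# ---------------------------------------------------------------------------
# GP imaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPImage:
    """Per-pixel generalized polarization.

    ``gp`` is NaN wherever the denominator I_ord + G·I_dis is at or below
    the floor; valid pixels lie in [−1, 1] by construction.
    """

    gp: np.ndarray
    g_factor: float
    ordered: np.ndarray  # I_500-580 source image
    disordered: np.ndarray  # I_620-750 source image

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.gp)


def compute_gp_image(
    ordered: np.ndarray,
    disordered: np.ndarray,
    g_factor: float = 1.0,
    denom_floor: float = 0.0,
) -> GPImage:
    """Pixel-wise GP = (I_ord − G·I_dis)/(I_ord + G·I_dis).

    Pixels whose denominator is ≤ ``denom_floor`` are masked (NaN).  With
    G = 1, swapping the channels negates GP at every pixel.
    """
    ordered = np.asarray(ordered, float)
    disordered = np.asarray(disordered, float)
    if ordered.shape != disordered.shape:
        raise ValueError("channel images must share a shape")
    if g_factor <= 0:
        raise ValueError("g_factor must be > 0")
    denom = ordered + g_factor * disordered
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = (ordered - g_factor * disordered) / denom
    gp = np.where(denom > denom_floor, gp, np.nan)
    return GPImage(
        gp=gp, g_factor=float(g_factor), ordered=ordered, disordered=disordered
    )


@dataclass(frozen=True)
class GPHistogramFit:
    """Single-Gaussian fit to the pixel-GP histogram of one region."""

    region: int
    peak: float  # fitted Gaussian mean (the region's characteristic GP)
    width: float  # fitted Gaussian sd
    r_squared: float
    n_pixels: int
    display_bin_edges: np.ndarray  # fixed [−1, 1] grid for reporting
    display_counts: np.ndarray
    fit: PeakFit


def fit_region_gp_peaks(
    gp_image: GPImage,
    mask: RegionMask,
    regions: Optional[Sequence[int]] = None,
    min_pixels: int = 100,
    display_bins: int = 64,
) -> list[GPHistogramFit]:
    """Characteristic GP per region from Gaussian-fitted pixel histograms.

    For each region the valid pixel GP values are histogrammed and fit with
    a single Gaussian (via :func:`memdyn.spt_dynamics.fit_peak_histogram`
    with ``allow_bimodal=False`` and data-driven binning); the fitted mean
    is the region's peak GP.  A fixed 64-bin histogram over [−1, 1] is also
    recorded for display/export.  Regions with fewer than ``min_pixels``
    valid pixels raise ``ValueError``.
    """
    if gp_image.gp.shape != mask.shape:
        raise ValueError("GP image and mask must share a shape")
    if regions is None:
        regions = [r for r in mask.present_labels() if r != 0]
    out = []
    for region in regions:
        sel = mask.region(region) & gp_image.valid
        values = gp_image.gp[sel]
        if len(values) < min_pixels:
            raise ValueError(
                f"region {region}: only {len(values)} valid GP pixels "
                f"(need >= {min_pixels})"
            )
        fit = fit_peak_histogram(values, allow_bimodal=False)
        comp = fit.components[0]
        disp_counts, disp_edges = np.histogram(
            values, bins=display_bins, range=(-1.0, 1.0)
        )
        out.append(
            GPHistogramFit(
                region=int(region),
                peak=float(np.clip(comp.peak, -1.0, 1.0)),
                width=comp.width,
                r_squared=fit.r_squared,
                n_pixels=int(len(values)),
                display_bin_edges=disp_edges,
                display_counts=disp_counts,
                fit=fit,
            )
        )
    return out


def calibrate_g_factor(
    i_ordered: float, i_disordered: float, gp_reference: float
) -> float:
    """Solve the GP formula for G given a reference sample of known GP.

    G = (I_ord / I_dis) · (1 − GP_ref) / (1 + GP_ref); requires
    GP_ref strictly inside (−1, 1) and positive channel means.
    """
    if not -1.0 < gp_reference < 1.0:
        raise ValueError("reference GP must be strictly inside (−1, 1)")
    if i_ordered <= 0 or i_disordered <= 0:
        raise ValueError("channel means must be positive")
    return (i_ordered / i_disordered) * (1 - gp_reference) / (1 + gp_reference)
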