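"""Endocytosis quantification from labeled cell images.

Quantities mirror the standard readouts of dye-uptake endocytosis assays:

* per-cell counts of internalized fluorescent puncta (endosomes),
* the mean intensity of those puncta and its ratio to the whole-cell mean
  ("relative internal intensity" — a dimensionless uptake index),
* plasma-membrane (PM) band intensity relative to a control group,
* percent changes between treatment groups, and two-sample Student's
  t-tests with the conventional significance flags (* p<0.05, ** p<0.01).

Region membership (PM band, cell interior, background) comes from a labeled
mask — ground-truth masks for synthetic data, or the simple ridge-based
:func:`segment_pm_band` helper for real images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage, stats

from .core import BACKGROUND, INTERIOR, PM, ImageStack, RegionMask
from .spt_dynamics import detect_spots

__all__ = [
    "PunctaQuant",
    "GroupStats",
    "GroupComparison",
    "quantify_puncta",
    "relative_pm_intensity",
    "percent_change",
    "compare_groups",
    "segment_pm_band",
]


@dataclass(frozen=True)
class PunctaQuant:
    """Per-cell endocytosis readouts.

    ``relative_internal_intensity`` is the mean over interior punctum
    footprint pixels divided by the mean over all PM ∪ interior pixels;
    it is typically in (0, 1) when the PM is the brightest structure.
    NaN intensity fields indicate a cell with no detected puncta.
    """

    cell_id: Union[int, str]
    n_puncta: int
    mean_internal_intensity: float
    relative_internal_intensity: float
    pm_mean_intensity: float


def _as_image(image: Union[np.ndarray, ImageStack]) -> tuple[np.ndarray, float]:
    if isinstance(image, ImageStack):
        if image.axes != "YX":
            raise ValueError("expected a single-plane YX image")
        return np.asarray(image.data, float), image.pixel_size_um
    return np.asarray(image, float), 1.0


def quantify_puncta(
    image: Union[np.ndarray, ImageStack],
    mask: RegionMask,
    pixel_size_um: Optional[float] = None,
    psf_sigma_um: float = 0.125,
    snr_threshold: float = 5.0,
    cell_id: Union[int, str] = 0,
) -> PunctaQuant:
    """Count and measure internalized puncta in one cell.

    Detection (LoG + Gaussian refinement, see
    :func:`memdyn.spt_dynamics.detect_spots`) is restricted to the interior
    label: pixels outside the interior are replaced by the interior median
    before filtering, so the bright PM band cannot spawn detections, and
    only spots whose centers fall on interior pixels are kept.  Punctum
    intensity is measured on the original image over a disk footprint of
    radius 2·psf_sigma around each center.
    """
    img, px_from_stack = _as_image(image)
    px = pixel_size_um if pixel_size_um is not None else px_from_stack
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    interior = mask.region(INTERIOR)
    if not interior.any():
        raise ValueError("interior label is empty")
    pm = mask.region(PM)

    work = np.where(interior, img, np.median(img[interior]))
    spots = detect_spots(
        work,
        px,
        psf_sigma_um=psf_sigma_um,
        snr_threshold=snr_threshold,
        region=interior,
    )

    cell = pm | interior
    pm_mean = float(img[pm].mean()) if pm.any() else np.nan
    cell_mean = float(img[cell].mean())

    n = len(spots)
    if n == 0:
        return PunctaQuant(cell_id, 0, np.nan, np.nan, pm_mean)

    footprint = np.zeros_like(img, dtype=bool)
    r_px = 2.0 * psf_sigma_um / px
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    for _, s in spots.iterrows():
        d2 = (yy - s["y_um"] / px) ** 2 + (xx - s["x_um"] / px) ** 2
        footprint |= d2 <= r_px**2
    footprint &= interior

    internal_mean = float(img[footprint].mean())
    return PunctaQuant(
        cell_id=cell_id,
        n_puncta=int(n),
        mean_internal_intensity=internal_mean,
        relative_internal_intensity=internal_mean / cell_mean,
        pm_mean_intensity=pm_mean,
    )


def relative_pm_intensity(
    treated_images: Sequence[Union[np.ndarray, ImageStack]],
    control_images: Sequence[Union[np.ndarray, ImageStack]],
    masks: Union[RegionMask, Sequence[RegionMask]],
) -> float:
    """PM-band intensity of a treated group as percent of control.

    Returns ``100 × mean(PM pixels, treated) / mean(PM pixels, control)``
    where the means pool all PM-labeled pixels across each group's images.
    ``masks`` may be one shared mask or one per image (treated followed by
    control order is irrelevant; each group is paired with its own masks if
    a sequence of ``len(treated)+len(control)`` masks is given).
    """
    if len(treated_images) == 0 or len(control_images) == 0:
        raise ValueError("both groups must be non-empty")
    if isinstance(masks, RegionMask):
        treated_masks = [masks] * len(treated_images)
        control_masks = [masks] * len(control_images)
    else:
        masks = list(masks)
        if len(masks) == len(treated_images) + len(control_images):
            treated_masks = masks[: len(treated_images)]
            control_masks = masks[len(treated_images) :]
        else:
            raise ValueError(
                "provide one shared mask or one mask per image "
                "(treated masks first)"
            )

    def pooled_pm_mean(images, group_masks) -> float:
        vals = []
        for im, m in zip(images, group_masks):
            img, _ = _as_image(im)
            pm = m.region(PM)
            if not pm.any():
                raise ValueError("PM label empty in a mask")
            vals.append(img[pm].ravel())
        return float(np.concatenate(vals).mean())

    control_mean = pooled_pm_mean(control_images, control_masks)
    if control_mean == 0:
        raise ZeroDivisionError("control PM intensity is zero")
    return 100.0 * pooled_pm_mean(treated_images, treated_masks) / control_mean


def percent_change(
    reference: Iterable[float], treated: Iterable[float]
) -> float:
    """Percent change of the treated group mean relative to the reference.

    ``100 × (mean(treated) − mean(reference)) / mean(reference)``; the
    reference mean must be non-zero.  Invariant under rescaling both groups
    by a common factor, and zero when the groups share a mean.
    """
    ref = np.asarray(list(reference), float)
    tre = np.asarray(list(treated), float)
    if len(ref) == 0 or len(tre) == 0:
        raise ValueError("both groups must be non-empty")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ZeroDivisionError("reference mean is zero")
    return 100.0 * (tre.mean() - ref_mean) / ref_mean


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    percent_change: float  # vs the reference group
    t_statistic: float
    p_value: float
    significance: str  # "", "*", or "**"


@dataclass(frozen=True)
class GroupComparison:
    reference: str
    groups: tuple[GroupStats, ...]

    def __getitem__(self, label: str) -> GroupStats:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def _significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    groups: Mapping[str, Iterable[float]],
    reference: str,
) -> GroupComparison:
    """Compare each group to a reference by equal-variance Student's t-test.

    Every group needs n ≥ 2.  SD is the sample standard deviation (ddof=1).
    The reference compared with itself reports t = 0, p = 1, no flag.
    Zero-variance pairs produce whatever t/p the test yields (possibly NaN);
    they are reported as computed.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not in groups")
    arrays = {k: np.asarray(list(v), float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    ref = arrays[reference]
    ref_mean = ref.mean()
    out = []
    for label, a in arrays.items():
        if label == reference:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, ref, equal_var=True)
            t, p = float(t), float(p)
            if a.shape == ref.shape and np.array_equal(a, ref):
                t, p = 0.0, 1.0
        pc = (
            100.0 * (a.mean() - ref_mean) / ref_mean if ref_mean != 0 else np.nan
        )
        out.append(
            GroupStats(
                label=label,
                n=len(a),
                mean=float(a.mean()),
                sd=float(a.std(ddof=1)),
                percent_change=float(pc),
                t_statistic=t,
                p_value=p,
                significance=_significance_flag(p) if label != reference else "",
            )
        )
    return GroupComparison(reference=reference, groups=tuple(out))


def segment_pm_band(
    image: Union[np.ndarray, ImageStack],
    smoothing_sigma_px: float = 2.0,
    band_quantile: float = 0.85,
) -> RegionMask:
    """Heuristic PM/interior/background segmentation for real images.

    The PM band is taken as the brightest closed ridge after Gaussian
    smoothing: pixels above the ``band_quantile`` intensity quantile form
    the band, its filled interior (minus the band) becomes the interior
    label, everything else background.  Intended as a convenience for raw
    micrographs; synthetic data carry exact masks.
    """
    img, _ = _as_image(image)
    smooth = ndimage.gaussian_filter(img, smoothing_sigma_px)
    band = smooth >= np.quantile(smooth, band_quantile)
    band = ndimage.binary_closing(band, iterations=2)
    filled = ndimage.binary_fill_holes(band)
    labels = np.full(img.shape, BACKGROUND, dtype=np.uint8)
    labels[band] = PM
    labels[filled & ~band] = INTERIOR
    return RegionMask(labels)
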