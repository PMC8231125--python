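"""Deposit segmentation and stain morphometry.

A dried droplet leaves a roughly circular deposit: a bright peripheral
ring pinned at the contact line, a dense textured "crown" annulus just
inside it, and a central region carrying crystalline aggregates. This
module finds the deposit, partitions it into the three analysis regions
(complete deposit, crown annulus, central disk), and measures the crown
thickness gamma and the superficial area of the central aggregate.

Segmentation is deliberately parameter-light: global Otsu thresholding
of the background-subtracted intensity, largest connected component,
morphological closing. Crown-class pixels are identified by a 3-class
Otsu split of the outer radial band (the middle class sits between the
deposit interior and the saturated ring), and gamma is the mean radial
extent of the crown class along 8 equally spaced rays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .texture import GrayImage

logger = logging.getLogger(__name__)

__all__ = [
    "StainGeometry",
    "RegionMasks",
    "CrownMeasurement",
    "AggregateMeasurement",
    "SegmentationError",
    "segment_stain",
    "partition_regions",
    "crown_thickness",
    "normalize_crown",
    "central_aggregate_area",
]


class SegmentationError(RuntimeError):
    """The image does not contain a segmentable deposit."""


@dataclass
class StainGeometry:
    """Deposit location and size.

    ``radius`` is the mean distance from the mask centroid to the mask
    boundary, in pixels; ``pixel_scale`` (mm per pixel), when supplied,
    converts measurements to millimetres downstream.
    """

    center: tuple[float, float]
    radius: float
    deposit_mask: np.ndarray
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.deposit_mask.any():
            raise ValueError("deposit mask is empty")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class RegionMasks:
    """The three analysis regions: complete deposit, crown annulus, center disk."""

    complete: np.ndarray
    crown: np.ndarray
    center: np.ndarray
    r_center: float
    r_in: float
    r_out: float

    def __post_init__(self) -> None:
        if (self.crown & self.center).any():
            raise ValueError("crown and center masks overlap")
        if (self.crown & ~self.complete).any() or (self.center & ~self.complete).any():
            raise ValueError("region masks must lie inside the complete deposit")


@dataclass
class CrownMeasurement:
    """Crown thickness gamma: mean of per-ray radial extents."""

    gamma: float
    ray_thicknesses: np.ndarray
    gamma_normalized: float | None = None
    no_crown: bool = False


@dataclass
class AggregateMeasurement:
    """Superficial area of the central crystalline aggregate."""

    area: float
    component_count: int


def _radial_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.indices(shape)
    return np.hypot(rr - center[0], cc - center[1])


def segment_stain(image: GrayImage, pixel_scale: float | None = None) -> StainGeometry:
    """Locate the deposit by Otsu thresholding of |intensity - background|.

    The background level is the median of the image border frame. The
    largest connected foreground component, closed and hole-filled, is
    the deposit; its centroid and mean centroid-to-boundary distance
    give the center and radius.
    """
    px = image.pixels.astype(float)
    h, w = px.shape
    border = np.concatenate([px[0], px[-1], px[1:-1, 0], px[1:-1, -1]])
    delta = np.abs(px - np.median(border))
    if delta.max() <= 1e-9:
        raise SegmentationError("blank image: no contrast against background")

    thr = threshold_otsu(delta)
    fg = delta > thr
    if not fg.any():
        raise SegmentationError("no foreground above the Otsu threshold")

    fg = ndimage.binary_closing(fg, structure=disk(3))
    fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()

    border_mask = np.zeros_like(mask)
    border_mask[0] = border_mask[-1] = True
    border_mask[:, 0] = border_mask[:, -1] = True
    n_border = border_mask.sum()
    if (mask & border_mask).sum() > 0.5 * n_border:
        raise SegmentationError("foreground touches more than half of the image border")

    rr, cc = np.nonzero(mask)
    center = (float(rr.mean()), float(cc.mean()))
    boundary = mask & ~ndimage.binary_erosion(mask)
    br, bc = np.nonzero(boundary)
    radius = float(np.hypot(br - center[0], bc - center[1]).mean())
    if radius <= 0:
        raise SegmentationError("degenerate deposit: zero radius")
    return StainGeometry(center=center, radius=radius, deposit_mask=mask,
                         pixel_scale=pixel_scale)


def partition_regions(
    image: GrayImage,
    geom: StainGeometry,
    fractions: tuple[float, float, float] = (0.5, 0.6, 0.95),
    auto_crown: bool = False,
) -> RegionMasks:
    """Split the deposit into center disk, crown annulus and complete mask.

    ``fractions = (f_center, f_in, f_out)`` express the center-disk
    radius and the crown annulus bounds as fractions of the deposit
    radius R. With ``auto_crown`` the annulus bounds are instead placed
    at the two largest-magnitude change points of the angularly-averaged
    radial median-intensity profile (searched inside the deposit, away
    from the outer ring edge).
    """
    f_center, f_in, f_out = fractions
    if not (0.0 < f_center <= f_in < f_out <= 1.0):
        raise ValueError("fractions must satisfy 0 < f_center <= f_in < f_out <= 1")

    r = _radial_grid(image.shape, geom.center)
    R = geom.radius
    if auto_crown:
        r_in, r_out = _auto_crown_bounds(image, geom)
        r_in = max(r_in, f_center * R)
    else:
        r_in, r_out = f_in * R, f_out * R

    complete = geom.deposit_mask
    center = complete & (r <= f_center * R)
    crown = complete & (r >= r_in) & (r <= r_out) & (r > f_center * R)
    return RegionMasks(complete=complete, crown=crown, center=center,
                       r_center=f_center * R, r_in=r_in, r_out=r_out)


def _auto_crown_bounds(image: GrayImage, geom: StainGeometry) -> tuple[float, float]:
    """Crown annulus bounds from the radial median-intensity profile.

    The profile is the per-1-px-radius-bin median intensity over the
    deposit. Its two largest-magnitude first differences inside
    [0.3R, 0.97R] — away from the center crystals and from the dominant
    ring/background edge at R — are taken as the crown boundaries.
    """
    r = _radial_grid(image.shape, geom.center)
    R = geom.radius
    inside = geom.deposit_mask
    bins = np.clip(r[inside].astype(int), 0, int(R))
    vals = image.pixels[inside].astype(float)
    profile = np.full(int(R) + 1, np.nan)
    for b in np.unique(bins):
        profile[b] = np.median(vals[bins == b])
    profile = np.nan_to_num(profile, nan=float(np.nanmedian(profile)))
    profile = ndimage.uniform_filter1d(profile, size=3)

    lo, hi = int(0.3 * R), int(0.97 * R)
    diffs = np.diff(profile)
    window = np.zeros_like(diffs, dtype=bool)
    window[lo:hi] = True
    mag = np.where(window, np.abs(diffs), -1.0)
    first = int(mag.argmax())
    mag[max(0, first - 3) : first + 4] = -1.0  # suppress the same edge
    second = int(mag.argmax())
    r_in, r_out = sorted((first + 0.5, second + 0.5))
    return float(r_in), float(r_out)


def _crown_class_bounds(
    image: GrayImage,
    geom: StainGeometry,
    f_center: float,
    min_class_contrast: float,
) -> tuple[float, float] | None:
    """Intensity interval of crown-class pixels, or None when absent.

    3-class Otsu on the outer radial band [f_center*R, R]; the middle
    class is the crown. The split is accepted only when the three class
    means are separated by at least ``min_class_contrast`` gray levels —
    otherwise the band is effectively bimodal (no crown).
    """
    r = _radial_grid(image.shape, geom.center)
    band = geom.deposit_mask & (r >= f_center * geom.radius)
    vals = image.pixels[band]
    if np.unique(vals).size < 3:
        return None
    try:
        t1, t2 = threshold_multiotsu(vals, classes=3)
    except ValueError:
        return None
    m0 = vals[vals < t1].mean() if (vals < t1).any() else t1
    m1 = vals[(vals >= t1) & (vals < t2)].mean() if ((vals >= t1) & (vals < t2)).any() else t1
    m2 = vals[vals >= t2].mean() if (vals >= t2).any() else t2
    if m1 - m0 < min_class_contrast or m2 - m1 < min_class_contrast:
        return None
    return float(t1), float(t2)


def crown_thickness(
    image: GrayImage,
    geom: StainGeometry,
    n_rays: int = 8,
    f_center: float = 0.5,
    step: float = 0.5,
    min_class_contrast: float = 10.0,
) -> CrownMeasurement:
    """Mean radial extent of crown-class pixels along ``n_rays`` rays.

    Rays start at 0 degrees and are equally spaced. Along each ray the
    intensity is sampled every ``step`` px from f_center*R out to R;
    the thickness is the radial extent of the densest contiguous
    stretch of crown-class samples (the maximum-score interval scoring
    crown +1 / non-crown -1), which tolerates brief texture excursions
    outside the crown intensity class. A ray with no crown samples contributes 0; when every ray
    is zero the stain is flagged as having no crown.
    """
    bounds = _crown_class_bounds(image, geom, f_center, min_class_contrast)
    R = geom.radius
    thicknesses = np.zeros(n_rays)
    if bounds is not None:
        t1, t2 = bounds
        h, w = image.shape
        radii = np.arange(f_center * R, R + step, step)
        for k in range(n_rays):
            theta = 2.0 * math.pi * k / n_rays
            rows = np.round(geom.center[0] - radii * math.sin(theta)).astype(int)
            cols = np.round(geom.center[1] + radii * math.cos(theta)).astype(int)
            ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
            rows, cols = rows[ok], cols[ok]
            vals = image.pixels[rows, cols].astype(float)
            in_mask = geom.deposit_mask[rows, cols]
            crown = (vals >= t1) & (vals < t2) & in_mask
            extent = _densest_interval(crown)
            thicknesses[k] = extent * step
            if extent == 0:
                logger.debug("ray %d: no crown-class pixels", k)

    gamma = float(thicknesses.mean())
    no_crown = bool(np.all(thicknesses == 0))
    if no_crown:
        logger.info("no crown detected: gamma = 0")
    return CrownMeasurement(gamma=gamma, ray_thicknesses=thicknesses, no_crown=no_crown)


def _densest_interval(flags: np.ndarray) -> int:
    """Length of the maximum-score interval (+1 in-class, -1 out).

    The optimal interval starts and ends on in-class samples, so its
    extent is the crown thickness including brief interior excursions.
    """
    if not flags.any():
        return 0
    best_score = score = 0
    best_len = run_start = 0
    for i, f in enumerate(flags):
        gain = 1 if f else -1
        if score <= 0:
            score, run_start = gain, i
        else:
            score += gain
        if f and score > best_score:
            best_score = score
            best_len = i - run_start + 1
    return best_len


def normalize_crown(gamma: float, gamma0: float) -> float:
    """Crown thickness relative to the unaltered-control thickness gamma0."""
    if gamma0 <= 0:
        raise ValueError("gamma0 must be positive")
    return gamma / gamma0


def central_aggregate_area(
    image: GrayImage,
    regions: RegionMasks,
    min_component: int = 25,
    min_contrast: float = 10.0,
) -> AggregateMeasurement:
    """Total pixel area of bright aggregates inside the center disk.

    Foreground is Otsu-thresholded within the center region; connected
    components smaller than ``min_component`` pixels are dropped. A
    featureless center (foreground/background means closer than
    ``min_contrast`` gray levels) reports zero area.
    """
    if not regions.center.any():
        raise ValueError("center region is empty")
    vals = image.pixels[regions.center].astype(float)
    if np.unique(vals).size < 2:
        return AggregateMeasurement(area=0.0, component_count=0)
    thr = threshold_otsu(vals)
    fg_vals = vals[vals > thr]
    bg_vals = vals[vals <= thr]
    if fg_vals.size == 0 or fg_vals.mean() - bg_vals.mean() < min_contrast:
        return AggregateMeasurement(area=0.0, component_count=0)

    fg = regions.center & (image.pixels > thr)
    labels = cc_label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes > min_component
    area = float(sizes[keep].sum())
    return AggregateMeasurement(area=area, component_count=int(keep.sum()))
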