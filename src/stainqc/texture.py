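"""Gray-level co-occurrence matrices and Haralick-style texture statistics.

The co-occurrence matrix is built over an arbitrary region mask: a pixel
pair at displacement (d, phi) contributes only when *both* endpoints fall
inside the mask, so texture can be measured on irregular regions such as a
crown annulus without rectangular cropping. Five scalar statistics are
derived from the normalized matrix: energy (angular second moment),
inertia (contrast), correlation, inverse difference moment and entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GrayImage",
    "GLCMConfig",
    "GLCMatrix",
    "MarginalStats",
    "TextureFeatures",
    "EmptyCooccurrenceError",
    "compute_glcm",
    "glcm_marginals",
    "texture_features",
    "requantize",
    "load_gray_image",
]

#: Unit-displacement (row, col) offsets for the four standard GLCM angles.
#: 0 deg points right along a row; 90 deg points up (toward smaller rows).
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


class EmptyCooccurrenceError(ValueError):
    """No pixel pair at the requested displacement lies inside the mask."""


@dataclass
class GrayImage:
    """Single-channel integer raster with an optional region mask.

    Parameters
    ----------
    pixels : ndarray of int, shape (H, W)
        Gray levels in ``[0, levels - 1]``, row-major, origin top-left.
    mask : ndarray of bool, shape (H, W), optional
        True marks pixels belonging to the analyzed region. ``None``
        means the whole frame.
    levels : int
        Number of gray levels Ng (256 for 8-bit input).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    levels: int = 256

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        if self.levels < 1:
            raise ValueError("levels must be positive")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() >= self.levels
        ):
            raise ValueError(
                f"intensities must lie in [0, {self.levels - 1}]"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must equal pixel shape")
            if not self.mask.any():
                raise ValueError("mask must contain at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_mask(self, mask: np.ndarray | None) -> "GrayImage":
        """Return the same raster restricted to a different region."""
        return GrayImage(self.pixels, mask=mask, levels=self.levels)


@dataclass(frozen=True)
class GLCMConfig:
    """Displacement and bookkeeping options for the co-occurrence matrix.

    ``d`` and ``phi`` default to the pipeline's reference displacement of
    2 pixels along the horizontal. ``symmetric=False`` counts ordered
    pairs only; enabling it adds the transposed count for every pair
    (classic Haralick symmetrization). ``entropy_log_base`` selects the
    logarithm used by the entropy statistic.
    """

    d: int = 2
    phi: int = 0
    symmetric: bool = False
    entropy_log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("displacement d must be >= 1")
        if self.phi not in ANGLE_OFFSETS:
            raise ValueError(f"phi must be one of {sorted(ANGLE_OFFSETS)}")
        if self.entropy_log_base not in ("natural", "2"):
            raise ValueError("entropy_log_base must be 'natural' or '2'")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = ANGLE_OFFSETS[self.phi]
        return dr * self.d, dc * self.d

    def log(self, x: np.ndarray) -> np.ndarray:
        return np.log2(x) if self.entropy_log_base == "2" else np.log(x)


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities with their raw counts."""

    p: np.ndarray
    counts: np.ndarray
    total_pairs: int

    def __post_init__(self) -> None:
        if self.total_pairs <= 0:
            raise ValueError("total_pairs must be positive")
        s = float(self.p.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {s}")

    @property
    def levels(self) -> int:
        return self.p.shape[0]


@dataclass(frozen=True)
class MarginalStats:
    """Means/SDs of the first (i) and second (j) index under p(i, j)."""

    ux: float
    uy: float
    sx: float
    sy: float


@dataclass(frozen=True)
class TextureFeatures:
    """The five co-occurrence statistics of one region.

    ``correlation`` is NaN (and ``correlation_defined`` False) when a
    marginal standard deviation vanishes, e.g. on a constant region.
    """

    energy: float
    inertia: float
    correlation: float
    idm: float
    entropy: float
    correlation_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "inertia": self.inertia,
            "correlation": self.correlation,
            "idm": self.idm,
            "entropy": self.entropy,
        }


def compute_glcm(image: GrayImage, config: GLCMConfig = GLCMConfig()) -> GLCMatrix:
    """Count gray-level pairs at displacement (d, phi) inside the mask.

    An ordered pair (a, b) contributes to ``counts[i, j]`` when pixel a
    has level i, pixel b — offset from a by d pixels in direction phi —
    has level j, and both lie inside the mask. Pairs straddling the mask
    border are discarded. With ``symmetric=True`` the reversed pair is
    counted as well before normalization.
    """
    px = image.pixels
    ng = image.levels
    h, w = px.shape
    dr, dc = config.offset

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise EmptyCooccurrenceError(
            f"displacement d={config.d}, phi={config.phi} exceeds image extent"
        )

    a = px[r0:r1, c0:c1]
    b = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if image.mask is not None:
        valid = image.mask[r0:r1, c0:c1] & image.mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    else:
        valid = np.ones(a.shape, dtype=bool)
    if not valid.any():
        raise EmptyCooccurrenceError(
            "no pixel pair at the requested displacement lies inside the mask"
        )

    flat = a[valid].astype(np.int64) * ng + b[valid].astype(np.int64)
    counts = np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    if config.symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    p = counts / total
    return GLCMatrix(p=p, counts=counts, total_pairs=total)


def glcm_marginals(glcm: GLCMatrix) -> MarginalStats:
    """Mean and standard deviation of each index of p(i, j).

    ux, sx weight the first index i; uy, sy the second index j. The SDs
    are square roots of the central second moments, so correlation built
    from them is bounded by [-1, 1].
    """
    p = glcm.p
    idx = np.arange(glcm.levels, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ux = float(idx @ pi)
    uy = float(idx @ pj)
    sx = float(math.sqrt(max(((idx - ux) ** 2) @ pi, 0.0)))
    sy = float(math.sqrt(max(((idx - uy) ** 2) @ pj, 0.0)))
    return MarginalStats(ux=ux, uy=uy, sx=sx, sy=sy)


def texture_features(
    glcm: GLCMatrix, config: GLCMConfig = GLCMConfig()
) -> TextureFeatures:
    """Energy, inertia, correlation, IDM and entropy of one GLCM.

    Zero-probability cells contribute nothing to the entropy
    (0 * log 0 := 0). When either marginal SD is zero the correlation is
    undefined and returned as NaN with ``correlation_defined=False``.
    """
    p = glcm.p
    ng = glcm.levels
    i = np.arange(ng, dtype=float)[:, None]
    j = np.arange(ng, dtype=float)[None, :]

    energy = float((p * p).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    nz = p[p > 0]
    entropy = float(-(nz * config.log(nz)).sum())
    entropy = max(entropy, 0.0)  # guard -0.0 from rounding

    m = glcm_marginals(glcm)
    denom = m.sx * m.sy
    if denom == 0.0:
        logger.debug("correlation undefined: a marginal SD is zero")
        return TextureFeatures(energy, inertia, float("nan"), idm, entropy, False)
    cor = float((((i * j) * p).sum() - m.ux * m.uy) / denom)
    return TextureFeatures(energy, inertia, cor, idm, entropy, True)


def requantize(image: GrayImage, levels: int) -> GrayImage:
    """Uniformly re-bin an image to a smaller number of gray levels."""
    if not 1 <= levels <= image.levels:
        raise ValueError("target levels must be in [1, current levels]")
    binned = (image.pixels.astype(np.int64) * levels) // image.levels
    return GrayImage(binned, mask=image.mask, levels=levels)


def load_gray_image(path, levels: int = 256) -> GrayImage:
    """Load a PNG/TIFF raster as an 8-bit single-channel :class:`GrayImage`.

    Multi-channel input is reduced by luminance average and re-quantized
    to 8 bits, with a logged notice.
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        logger.info("multi-channel image %s reduced by luminance average", path)
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype != np.uint8:
        arr = arr.astype(float)
        if arr.min() < 0 or arr.max() > 255:
            lo, hi = float(arr.min()), float(arr.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            arr = (arr - lo) * scale
            logger.info("image %s re-quantized to 8 bit", path)
        arr = np.rint(arr)
    return GrayImage(np.asarray(arr).astype(np.uint8), levels=levels)
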