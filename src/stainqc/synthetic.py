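"""Seeded generator of synthetic dried-droplet stain images.

Real drug deposits are not publicly available, so the pipeline is
exercised on procedurally generated stains that reproduce the
structural trends the analysis relies on: a bright peripheral ring at
the pinned contact line, a textured crown annulus whose thickness
shrinks as the drug is diluted, a central crystalline aggregate whose
area grows with dilution, and crown texture whose spatial correlation
length grows (hence whose co-occurrence entropy falls) with dilution.

Every image is a deterministic function of its parameters and seed;
group generation derives per-image seeds from a master seed, so whole
experiments are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .texture import GrayImage

__all__ = [
    "StainParams",
    "StainGroundTruth",
    "dilution_map",
    "render_stain",
    "make_group",
]

# Dilution-response coefficients: fractional crown shrinkage at full
# dilution, relative texture-correlation-length growth, and relative
# aggregate-area growth. Chosen so the far end of the dilution axis is
# cleanly separable while neighbouring dilutions overlap.
CROWN_SHRINK = 0.8
TEXTURE_GROWTH = 2.0
AREA_GROWTH = 1.0


@dataclass(frozen=True)
class StainParams:
    """Geometry, intensity and noise parameters of one synthetic stain.

    Lengths are in pixels, intensities in 8-bit gray levels.

    ``crown_texture_scale`` is the Gaussian correlation length of the
    band-limited noise texturing the crown. ``texture_jitter`` and
    ``gamma_jitter`` are lognormal sds of per-image multiplicative
    jitter on the texture scale and crown thickness — the
    stain-to-stain variability that makes neighbouring dilutions
    overlap while distant ones separate cleanly. ``dilution`` in [0, 1]
    is the fraction of added water-like agent.
    """

    image_size: int = 384
    radius: float = 150.0
    ring_width: float = 10.0
    crown_thickness: float = 30.0
    crown_texture_scale: float = 1.5
    crown_texture_sd: float = 10.0
    texture_jitter: float = 0.4
    gamma_jitter: float = 0.08
    crystal_count: int = 3
    crystal_area: float = 5000.0
    background_level: float = 20.0
    deposit_level: float = 90.0
    crown_level: float = 150.0
    ring_level: float = 230.0
    crystal_level: float = 200.0
    noise_sd: float = 2.0
    dilution: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dilution <= 1.0:
            raise ValueError("dilution must lie in [0, 1]")
        if self.crown_thickness < 0:
            raise ValueError("crown_thickness must be >= 0")
        if self.radius + self.ring_width >= self.image_size / 2:
            raise ValueError("deposit plus ring must fit inside the image")
        if self.radius - self.ring_width - self.crown_thickness < 0:
            raise ValueError("crown would cross the deposit center")
        for name in ("background_level", "deposit_level", "crown_level",
                     "ring_level", "crystal_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.crown_texture_scale <= 0:
            raise ValueError("crown_texture_scale must be positive")
        if self.noise_sd < 0 or self.crown_texture_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.texture_jitter < 0 or self.gamma_jitter < 0:
            raise ValueError("jitter sds must be >= 0")


@dataclass(frozen=True)
class StainGroundTruth:
    """What was actually rendered, for recovery tests and manifests."""

    gamma_true: float
    crystal_area_true: float
    radius: float
    r_crown_inner: float
    r_crown_outer: float
    texture_scale_effective: float
    seed: int


def dilution_map(base: StainParams, s: float) -> StainParams:
    """Deterministic parameter response to dilution fraction ``s``.

    Crown thickness shrinks linearly to 20% of its undiluted value at
    s = 1; the crown texture correlation length triples (smoother
    texture, lower co-occurrence entropy); the aggregate area doubles.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("dilution fraction must lie in [0, 1]")
    return dataclasses.replace(
        base,
        crown_thickness=base.crown_thickness * (1.0 - CROWN_SHRINK * s),
        crown_texture_scale=base.crown_texture_scale * (1.0 + TEXTURE_GROWTH * s),
        crystal_area=base.crystal_area * (1.0 + AREA_GROWTH * s),
        dilution=s,
    )


def render_stain(params: StainParams) -> tuple[GrayImage, StainGroundTruth]:
    """Render one stain image; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    c = (n - 1) / 2.0
    rr, cc = np.indices((n, n))
    dist = np.hypot(rr - c, cc - c)

    R = params.radius
    r_ring_in = R - params.ring_width
    gamma_eff = params.crown_thickness
    if params.gamma_jitter > 0 and gamma_eff > 0:
        gamma_eff = min(gamma_eff * math.exp(rng.normal(0.0, params.gamma_jitter)),
                        r_ring_in)
    r_crown_in = r_ring_in - gamma_eff

    img = np.full((n, n), params.background_level, dtype=float)
    img[dist <= R] = params.deposit_level
    crown = (dist >= r_crown_in) & (dist < r_ring_in)
    img[crown] = params.crown_level
    img[(dist >= r_ring_in) & (dist <= R)] = params.ring_level

    # Band-limited crown texture: smoothed white noise rescaled to a
    # fixed sd so only the spatial correlation varies with dilution.
    scale_eff = params.crown_texture_scale
    if params.texture_jitter > 0:
        scale_eff *= math.exp(rng.normal(0.0, params.texture_jitter))
    if params.crown_texture_sd > 0 and crown.any():
        field = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=scale_eff)
        sd = field[crown].std()
        if sd > 0:
            img[crown] += field[crown] * (params.crown_texture_sd / sd)

    crystal_mask = _draw_crystals(rng, (n, n), (c, c), 0.45 * R,
                                  params.crystal_count, params.crystal_area)
    img[crystal_mask] = params.crystal_level
    area_true = float(crystal_mask.sum())

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = StainGroundTruth(
        gamma_true=gamma_eff,
        crystal_area_true=area_true,
        radius=R,
        r_crown_inner=r_crown_in,
        r_crown_outer=r_ring_in,
        texture_scale_effective=scale_eff,
        seed=params.seed,
    )
    return GrayImage(pixels), truth


def _draw_crystals(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    placement_radius: float,
    count: int,
    total_area: float,
) -> np.ndarray:
    """Paint ``count`` star-polygon motifs totalling about ``total_area`` px.

    Crystals are placed at equally spaced angles (with jitter) around
    the deposit center so they stay inside the central analysis disk.
    The returned mask is the union of the painted polygons; its pixel
    count is the ground-truth aggregate area.
    """
    mask = np.zeros(shape, dtype=bool)
    if count < 1 or total_area <= 0:
        return mask
    per_area = total_area / count
    for k in range(count):
        arms = int(rng.integers(5, 10))
        # star polygon with alternating radii ro, ri = 0.4*ro:
        # area = arms * ro * ri * sin(pi/arms)
        ro = math.sqrt(per_area / (0.4 * arms * math.sin(math.pi / arms)))
        if count == 1:
            pr, pc = center
        else:
            theta = 2.0 * math.pi * k / count + rng.uniform(-0.2, 0.2)
            rad = rng.uniform(0.35, 0.75) * max(placement_radius - ro, 0.0)
            pr = center[0] - rad * math.sin(theta)
            pc = center[1] + rad * math.cos(theta)
        phase = rng.uniform(0, 2 * math.pi)
        angles = phase + np.arange(2 * arms) * math.pi / arms
        radii = np.where(np.arange(2 * arms) % 2 == 0, ro, 0.4 * ro)
        poly_r = pr + radii * np.sin(angles)
        poly_c = pc + radii * np.cos(angles)
        fr, fc = draw_polygon(poly_r, poly_c, shape=shape)
        mask[fr, fc] = True
    return mask


def make_group(
    base: StainParams, s: float, n: int, master_seed: int
) -> list[tuple[GrayImage, StainGroundTruth]]:
    """Generate ``n`` stains at dilution ``s`` with reproducible seeds.

    Per-image seeds are drawn from a generator seeded by
    ``master_seed``, so the same master seed always yields the same
    group, independent of any global RNG state.
    """
    if n < 1:
        raise ValueError("group size must be >= 1")
    params = dilution_map(base, s)
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n)
    return [render_stain(dataclasses.replace(params, seed=int(sd))) for sd in seeds]
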