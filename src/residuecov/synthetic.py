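"""Synthetic ground scenes with exact residue/vegetation ground truth.

Emulates field photographs of wheat stubble: a soil-colored background
with per-pixel color noise, elongated pale straw strokes laid down
until a target residue fraction is reached, and optional distractors —
green vegetation patches, gray stones, and darkened shadow regions.
Straws are hard-edged rotated rectangles (no anti-aliasing), so the
ground-truth residue mask is exact at pixel level; exactness is what
the tests need, not photorealism.

Rendering order: soil, shadows (a multiplicative darkening of what is
below them), stones, vegetation, straws. Later layers overwrite
earlier ones in the color image, and the vegetation ground truth keeps
only vegetation pixels still visible under the straws — the masks
always describe the rendered image.

Every output is a deterministic function of the spec (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import ellipse, polygon

from .segmentation import DEFAULT_VEGETATION, SegmentationParams, VegetationParams, segment

__all__ = ["SceneSpec", "generate_scene", "generate_consistent_pair"]

RGB = tuple[float, float, float]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Color means/sds are 8-bit intensities; fractions are of total image
    area. ``n_straws`` caps how many strokes may be drawn while chasing
    ``residue_target_fraction``. When the straw size ranges are left
    unset they scale with the image (length 15–50% of the shorter side,
    width about 1–3%), so a 640x480 scene gets straws proportionate to
    the field photographs and a small test scene stays drawable.
    """

    height: int = 480
    width: int = 640
    residue_target_fraction: float = 0.5
    n_straws: int = 2000
    straw_length_range: Optional[tuple[int, int]] = None
    straw_width_range: Optional[tuple[int, int]] = None
    soil_color_mean: RGB = (120.0, 95.0, 70.0)
    soil_color_sd: RGB = (15.0, 15.0, 15.0)
    straw_color_mean: RGB = (210.0, 175.0, 150.0)
    straw_color_sd: RGB = (15.0, 15.0, 15.0)
    vegetation_color_mean: RGB = (60.0, 140.0, 50.0)
    vegetation_color_sd: RGB = (15.0, 15.0, 15.0)
    vegetation_fraction: float = 0.1
    n_stones: int = 5
    stone_color_mean: RGB = (150.0, 145.0, 138.0)
    shadow_fraction: float = 0.1
    shadow_strength: float = 0.45
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene dimensions must be at least 16x16")
        for name in ("residue_target_fraction", "vegetation_fraction", "shadow_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("soil_color_mean", "straw_color_mean",
                     "vegetation_color_mean", "stone_color_mean"):
            if not all(0.0 <= c <= 255.0 for c in getattr(self, name)):
                raise ValueError(f"{name} channels must be in [0, 255]")
        if self.residue_target_fraction > 0.0 and self.n_straws == 0:
            raise ValueError(
                "residue_target_fraction > 0 is infeasible with n_straws = 0")

    def _straw_length(self) -> tuple[int, int]:
        if self.straw_length_range is not None:
            return self.straw_length_range
        short = min(self.height, self.width)
        return (max(4, round(0.15 * short)), max(6, round(0.5 * short)))

    def _straw_width(self) -> tuple[int, int]:
        if self.straw_width_range is not None:
            return self.straw_width_range
        short = min(self.height, self.width)
        return (max(1, round(0.01 * short)), max(2, round(0.03 * short)))


def _color_noise(rng, shape, sd) -> np.ndarray:
    """Per-pixel Gaussian color noise, luminance-dominant.

    Under uncontrolled field lighting most surface variation is
    brightness, not hue: the noise is a shared luminance term across
    the three channels plus a smaller independent chroma term, with
    per-channel standard deviation equal to ``sd``. A hue-stable
    surface keeps linear color indices (such as excess green)
    well-behaved, which is what makes the scenes segmentable at all.
    """
    sd = np.broadcast_to(np.asarray(sd, dtype=np.float64), (3,))
    lum = rng.standard_normal(shape[:-1])[..., None]
    chroma = rng.standard_normal(shape)
    w = np.sqrt(0.9)  # 90% of the variance is luminance
    return (w * lum + np.sqrt(1 - w**2) * chroma) * sd


def _paint(img, rr, cc, mean, sd, rng) -> None:
    img[rr, cc] = np.asarray(mean) + _color_noise(rng, (len(rr), 3), sd)


def _random_ellipse(rng, h, w):
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    short = min(h, w)
    ra = rng.uniform(0.05, 0.18) * short
    rb = rng.uniform(0.05, 0.18) * short
    theta = rng.uniform(0, np.pi)
    return ellipse(r0, c0, ra, rb, shape=(h, w), rotation=theta)


def _random_straw(rng, spec: SceneSpec):
    h, w = spec.height, spec.width
    lo_l, hi_l = spec._straw_length()
    lo_w, hi_w = spec._straw_width()
    length = rng.uniform(lo_l, hi_l)
    width = rng.uniform(lo_w, hi_w)
    theta = rng.uniform(0, np.pi)
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    # axis vectors of the rotated rectangle
    dr, dc = np.sin(theta), np.cos(theta)
    pr, pc = -dc, dr
    half_l, half_w = length / 2.0, width / 2.0
    corners_r = [r0 + s * half_l * dr + t * half_w * pr
                 for s, t in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    corners_c = [c0 + s * half_l * dc + t * half_w * pc
                 for s, t in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    return polygon(corners_r, corners_c, shape=(h, w))


def _fill_fraction(rng, spec, target_fraction, draw_one, mask, max_attempts):
    """Accumulate random shapes into ``mask`` until it covers the target."""
    total = spec.height * spec.width
    target = target_fraction * total
    attempts = 0
    regions = []
    while np.count_nonzero(mask) < target and attempts < max_attempts:
        rr, cc = draw_one(rng)
        if len(rr):
            mask[rr, cc] = True
            regions.append((rr, cc))
        attempts += 1
    return regions


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one scene.

    Returns
    -------
    (image, residue_mask, vegetation_mask) :
        HxWx3 uint8 image and two HxW uint8 {0,1} ground-truth masks.
        The masks are disjoint: straws drawn over vegetation claim
        those pixels for residue.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.asarray(spec.soil_color_mean) + _color_noise(rng, (h, w, 3),
                                                          spec.soil_color_sd)

    if spec.shadow_fraction > 0.0:
        shadow = np.zeros((h, w), dtype=bool)
        _fill_fraction(rng, spec, spec.shadow_fraction,
                       lambda r: _random_ellipse(r, h, w), shadow,
                       max_attempts=200)
        img[shadow] *= spec.shadow_strength

    for _ in range(spec.n_stones):
        rr, cc = _random_ellipse(rng, h, w)
        if len(rr):
            _paint(img, rr, cc, spec.stone_color_mean, 8.0, rng)

    veg = np.zeros((h, w), dtype=bool)
    if spec.vegetation_fraction > 0.0:
        regions = _fill_fraction(rng, spec, spec.vegetation_fraction,
                                 lambda r: _random_ellipse(r, h, w), veg,
                                 max_attempts=200)
        for rr, cc in regions:
            _paint(img, rr, cc, spec.vegetation_color_mean,
                   spec.vegetation_color_sd, rng)

    residue = np.zeros((h, w), dtype=bool)
    if spec.residue_target_fraction > 0.0:
        regions = _fill_fraction(rng, spec, spec.residue_target_fraction,
                                 lambda r: _random_straw(r, spec), residue,
                                 max_attempts=spec.n_straws)
        for rr, cc in regions:
            _paint(img, rr, cc, spec.straw_color_mean, spec.straw_color_sd, rng)

    veg &= ~residue  # only still-visible vegetation counts

    if spec.noise_sd > 0.0:
        img += _color_noise(rng, img.shape, spec.noise_sd)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, residue.astype(np.uint8), veg.astype(np.uint8)


def generate_consistent_pair(
    params: SegmentationParams,
    veg: VegetationParams = DEFAULT_VEGETATION,
    spec: SceneSpec = SceneSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Scene plus a template that IS the segmentation output under ``params``.

    By construction the tuner's objective has a global optimum of
    exactly zero at the generating parameters, which makes the pair a
    controlled fixture for convergence and oracle tests.
    """
    img, _, _ = generate_scene(spec)
    template = segment(img, params, veg)
    return img, template
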