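"""Color-index segmentation of crop residue in RGB field images.

The residue classifier is a linear combination of the three color planes
followed by a hard threshold::

    gris(i, j) = c_r * R(i, j) + c_g * G(i, j) + c_b * B(i, j)
    binaria(i, j) = 1  if gris(i, j) > threshold else 0

The full procedure adds a vegetation-removal step: a second
linear-combination index (by default excess green, 2G - R - B) detects
green plant cover, whose pixels are subtracted from the residue
candidate mask; a 5x5 median filter then removes speckle noise.

Gray values are deliberately *not* clipped to [0, 255]: with signed
coefficients the index routinely leaves that range, and the strict
``>`` comparison makes the final mask invariant under any positive
rescaling of (c_r, c_g, c_b, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "VegetationParams",
    "TABLE1",
    "DEFAULT_VEGETATION",
    "PRESETS",
    "linear_combination",
    "threshold_image",
    "vegetation_mask",
    "subtract_mask",
    "median_filter_5x5",
    "segment",
    "params_from_dict",
    "config_from_dict",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Coefficients of the RGB linear combination plus the binarization cut.

    c_r, c_g, c_b are dimensionless channel weights; threshold is a cut
    value on the (unclipped) gray index. Tuned values are bounded to
    [-10, 10] for coefficients and [0, 255] for the threshold.
    """

    c_r: float
    c_g: float
    c_b: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("c_r", "c_g", "c_b", "threshold"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def coefficients(self) -> np.ndarray:
        return np.array([self.c_r, self.c_g, self.c_b], dtype=np.float64)

    def as_dict(self) -> dict:
        return asdict(self)

    def scaled(self, k: float) -> "SegmentationParams":
        """All four fields multiplied by ``k`` (mask-invariant for k > 0)."""
        return type(self)(self.c_r * k, self.c_g * k, self.c_b * k, self.threshold * k)


class VegetationParams(SegmentationParams):
    """Same quadruple applied to detect green vegetation (1 = vegetation)."""


#: Segmentation parameters tuned in the original field study (20-image
#: training set of 640x480 photographs of wheat stubble on soil).
TABLE1 = SegmentationParams(c_r=-8.3675, c_g=0.7128, c_b=8.9926, threshold=93.316)

#: Excess-green index (2G - R - B) with a cut at 20 -- the standard
#: green-cover detector in field-image analysis.
DEFAULT_VEGETATION = VegetationParams(c_r=-1.0, c_g=2.0, c_b=-1.0, threshold=20.0)

PRESETS: dict[str, SegmentationParams] = {"table1": TABLE1}


def _as_rgb_array(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    return img


def linear_combination(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Weighted sum of the R, G, B planes; float64, not clipped."""
    img = _as_rgb_array(img)
    r = img[..., 0].astype(np.float64)
    g = img[..., 1].astype(np.float64)
    b = img[..., 2].astype(np.float64)
    return params.c_r * r + params.c_g * g + params.c_b * b


def threshold_image(gray: np.ndarray, threshold: float) -> np.ndarray:
    """Binarize: 1 strictly above ``threshold``, 0 at or below it."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected an HxW gray image, got shape {gray.shape}")
    return (gray > threshold).astype(np.uint8)


def vegetation_mask(img: np.ndarray, veg: VegetationParams = DEFAULT_VEGETATION) -> np.ndarray:
    """Binary mask of green plant cover (1 = vegetation)."""
    return threshold_image(linear_combination(img, veg), veg.threshold)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")


def subtract_mask(residue_candidate: np.ndarray, vegetation: np.ndarray) -> np.ndarray:
    """Remove vegetation pixels from the residue candidate (never negative)."""
    residue_candidate = np.asarray(residue_candidate)
    vegetation = np.asarray(vegetation)
    _check_same_shape(residue_candidate, vegetation)
    return ((residue_candidate > 0) & (vegetation == 0)).astype(np.uint8)


_BOX5 = np.ones(5, dtype=np.int32)


def median_filter_5x5(mask: np.ndarray) -> np.ndarray:
    """5x5 median filter for binary masks (majority vote over the window).

    For {0, 1} input the window median equals "more than 12 of the 25
    samples are 1", computed here as a separable box count in exact
    integer arithmetic. Borders are handled by edge replication, so
    every window still holds 25 (partially repeated) samples and ties
    are impossible.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an HxW mask, got shape {mask.shape}")
    m = (mask > 0).astype(np.int32)
    counts = ndimage.correlate1d(m, _BOX5, axis=0, mode="nearest")
    counts = ndimage.correlate1d(counts, _BOX5, axis=1, mode="nearest")
    return (counts > 12).astype(np.uint8)


def segment(
    img: np.ndarray,
    params: SegmentationParams,
    veg: VegetationParams = DEFAULT_VEGETATION,
    apply_median: bool = True,
    median_vegetation: bool = False,
) -> np.ndarray:
    """Full residue segmentation: index + threshold, vegetation subtraction,
    optional 5x5 median filtering of the final mask.

    Parameters
    ----------
    img : HxWx3 uint8 array
        RGB input image.
    params : SegmentationParams
        Residue index coefficients and threshold.
    veg : VegetationParams
        Vegetation index used for the subtraction step.
    apply_median : bool
        Median-filter the final residue mask (default on).
    median_vegetation : bool
        Also median-filter the vegetation mask before subtraction.

    Returns
    -------
    HxW uint8 mask, 1 = residue.
    """
    candidate = threshold_image(linear_combination(img, params), params.threshold)
    green = vegetation_mask(img, veg)
    if median_vegetation:
        green = median_filter_5x5(green)
    residue = subtract_mask(candidate, green)
    if apply_median:
        residue = median_filter_5x5(residue)
    return residue


# -- configuration plumbing -------------------------------------------------

def params_from_dict(d: Mapping, cls=SegmentationParams) -> SegmentationParams:
    """Build params from ``{"coefficients": {c_r, c_g, c_b}, "threshold": t}``
    or a flat ``{c_r, c_g, c_b, threshold}`` mapping."""
    if "coefficients" in d:
        coef = d["coefficients"]
        return cls(float(coef["c_r"]), float(coef["c_g"]), float(coef["c_b"]),
                   float(d["threshold"]))
    return cls(float(d["c_r"]), float(d["c_g"]), float(d["c_b"]), float(d["threshold"]))


def config_from_dict(d: Mapping) -> tuple[SegmentationParams, VegetationParams, bool]:
    """Parse a segmentation config mapping.

    Recognized keys: ``preset`` (name in :data:`PRESETS`) or
    ``coefficients``/``threshold``; ``vegetation`` (same shape);
    ``apply_median`` (default true).
    """
    if "preset" in d:
        params = PRESETS[d["preset"]]
    else:
        params = params_from_dict(d)
    veg = (params_from_dict(d["vegetation"], cls=VegetationParams)
           if "vegetation" in d else DEFAULT_VEGETATION)
    apply_median = bool(d.get("apply_median", True))
    return params, veg, apply_median
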