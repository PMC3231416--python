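"""Raster I/O for RGB scenes and binary residue masks.

Internal conventions: images are HxWx3 uint8 arrays (row, column,
channel; origin top-left); masks are HxW uint8 arrays of {0, 1} with
1 = foreground (residue, or vegetation depending on context). Masks are
written as 8-bit grayscale PNG with foreground white (255), matching
the field convention of showing residue in white.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize_local_mean

__all__ = ["read_rgb", "read_template", "write_mask", "resize_image"]


def _load(path) -> np.ndarray:
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # decoders raise a zoo of error types
        raise ValueError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.round(arr / 257.0).astype(np.uint8)  # 65535 -> 255
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)
    info = np.iinfo(arr.dtype)
    scaled = (arr.astype(np.float64) - info.min) * (255.0 / (info.max - info.min))
    return np.round(scaled).astype(np.uint8)


def read_rgb(path) -> np.ndarray:
    """Read a raster file as an HxWx3 uint8 RGB image.

    Grayscale files are replicated across channels; alpha channels are
    dropped; 16-bit data is rescaled to [0, 255].
    """
    arr = _to_uint8(_load(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported image layout {arr.shape} in {os.fspath(path)!r}")
    return np.ascontiguousarray(arr)


def read_template(path, foreground: str = "dark") -> np.ndarray:
    """Read a scanned/stored template as a binary mask with 1 = residue.

    The file is converted to grayscale and cut at mid-scale (>= 128 is
    bright). ``foreground`` says which side marks residue: ``"dark"``
    for marker-ink tracings on white paper, ``"bright"`` for white-on-
    black mask images (the format :func:`write_mask` produces).
    """
    if foreground not in ("dark", "bright"):
        raise ValueError(f"foreground must be 'dark' or 'bright', got {foreground!r}")
    arr = _to_uint8(_load(path))
    if arr.ndim == 3:
        arr = arr[:, :, :3].mean(axis=2)
    bright = arr >= 128
    mask = ~bright if foreground == "dark" else bright
    return mask.astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as an 8-bit grayscale image (1 -> white 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an HxW mask, got shape {mask.shape}")
    iio.imwrite(path, ((mask > 0) * np.uint8(255)))


def resize_image(img: np.ndarray, new_h: int, new_w: int) -> np.ndarray:
    """Area-average resampling of an RGB image to (new_h, new_w)."""
    if new_h < 1 or new_w < 1:
        raise ValueError(f"target dimensions must be >= 1, got ({new_h}, {new_w})")
    img = np.asarray(img)
    out = resize_local_mean(img.astype(np.float64), (new_h, new_w, img.shape[2])
                            if img.ndim == 3 else (new_h, new_w))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
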