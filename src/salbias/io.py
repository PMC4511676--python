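"""Image / mask / map file plumbing (8-bit PNG conventions)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._utils import as_float_rgb, minmax_normalize

__all__ = ["read_image", "read_mask", "write_image", "write_mask", "write_map", "read_map"]

MASK_THRESHOLD = 127  # foreground = value > 127 in an 8-bit mask


def read_image(path) -> np.ndarray:
    """Load an RGB image as float in [0, 1]."""
    return as_float_rgb(iio.imread(path))


def read_mask(path) -> np.ndarray:
    """Load an 8-bit grayscale mask; foreground is any value > 127."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > MASK_THRESHOLD


def write_image(path, image) -> None:
    iio.imwrite(Path(path), (np.clip(image, 0, 1) * 255).round().astype(np.uint8))


def write_mask(path, mask) -> None:
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_map(path, smap, float_container: bool = False) -> None:
    """Write a saliency map as min-max-scaled 8-bit PNG (optionally also .npy)."""
    path = Path(path)
    scaled = minmax_normalize(smap, warn_constant=False)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
    if float_container:
        np.save(path.with_suffix(".npy"), np.asarray(smap, dtype=np.float32))


def read_map(path) -> np.ndarray:
    """Load a saliency map; prefers the float container when present."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    if npy.exists():
        return np.load(npy).astype(float)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float) / 255.0
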