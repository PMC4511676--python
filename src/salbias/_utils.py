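"""Small shared helpers."""

from __future__ import annotations

import warnings

import numpy as np

SIGMA_X_FRAC = float(np.sqrt(0.0223))  # default x std dev, fraction of image width
SIGMA_Y_FRAC = float(np.sqrt(0.0214))  # default y std dev, fraction of image height


def minmax_normalize(values, warn_constant: bool = True) -> np.ndarray:
    """Scale an array to [0, 1]; constant input maps to all zeros."""
    v = np.asarray(values, dtype=float)
    lo = v.min()
    hi = v.max()
    if hi == lo:
        if warn_constant:
            warnings.warn("constant values: normalized map is all zeros")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def as_float_rgb(image) -> np.ndarray:
    """Coerce an image to float RGB in [0, 1] (accepts uint8 and grayscale)."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image")
    img = img[..., :3]
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    img = img.astype(float)
    if img.max() > 1.0 + 1e-9:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)
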