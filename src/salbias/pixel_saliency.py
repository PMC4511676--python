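"""Pixel-based maximum-symmetric-surround (MSSS) saliency.

Each pixel is scored by the Euclidean Lab distance between its (slightly
smoothed) color and the mean color of its *maximum symmetric surround*:
the largest image-contained rectangle centered on the pixel.  Near the
borders the surround shrinks symmetrically, which keeps the center/
surround comparison balanced everywhere and sharpens object boundaries
relative to a fixed global surround.  Window means are computed with a
summed-area table, so the cost is linear in the pixel count.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d
from skimage import color as skcolor
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import SIGMA_X_FRAC, SIGMA_Y_FRAC, as_float_rgb, minmax_normalize
from .center_bias import GaussianCenterBias
from .fusion import FusionSpec, combine

__all__ = ["MaximumSymmetricSurround", "msss_saliency", "msss_cb_saliency"]

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _surround_means(channel: np.ndarray) -> np.ndarray:
    """Mean over the maximum symmetric surround window of every pixel."""
    m, n = channel.shape
    ii = np.arange(m)[:, None]
    jj = np.arange(n)[None, :]
    y0 = np.minimum(ii, m - 1 - ii)
    x0 = np.minimum(jj, n - 1 - jj)
    sat = np.zeros((m + 1, n + 1))
    sat[1:, 1:] = channel.cumsum(axis=0).cumsum(axis=1)
    top = ii - y0
    bot = ii + y0 + 1
    left = jj - x0
    right = jj + x0 + 1
    total = (sat[bot, right] - sat[top, right] - sat[bot, left] + sat[top, left])
    area = (2 * y0 + 1) * (2 * x0 + 1)
    return total / area


class MaximumSymmetricSurround(TransformerMixin, BaseEstimator):
    """MSSS bottom-up saliency estimator (optionally center-bias fused).

    Parameters
    ----------
    smooth : bool
        Smooth the per-pixel Lab color with a 5x5 binomial kernel
        (border-replicated) before the surround comparison.
    squared_distance : bool
        Score with the squared Lab distance instead of the Euclidean norm.
    center_bias : str or None
        Fusion scheme for an explicit Gaussian center-bias map; None
        disables it.  ``wc = 1`` with the convex scheme yields the
        standalone pixel center-bias model.
    wc, weighted_extrema, sigma_x_frac, sigma_y_frac :
        Fusion weight and center-bias parameters, as in
        :class:`~salbias.region_saliency.RegionContrast`.
    """

    def __init__(self, smooth: bool = True, squared_distance: bool = False,
                 center_bias: str | None = None, wc: float = 0.25,
                 weighted_extrema: bool = False,
                 sigma_x_frac: float = SIGMA_X_FRAC,
                 sigma_y_frac: float = SIGMA_Y_FRAC):
        self.smooth = smooth
        self.squared_distance = squared_distance
        self.center_bias = center_bias
        self.wc = wc
        self.weighted_extrema = weighted_extrema
        self.sigma_x_frac = sigma_x_frac
        self.sigma_y_frac = sigma_y_frac

    def fit(self, X=None, y=None):
        FusionSpec(self.center_bias or "convex", self.wc)  # validate
        self.n_features_in_ = 0
        return self

    def bottom_up(self, image) -> np.ndarray:
        """Min-max-normalized MSSS map without any center bias."""
        img = as_float_rgb(image)
        if min(img.shape[:2]) < 3:
            raise ValueError("image sides must be at least 3 pixels")
        lab = skcolor.rgb2lab(img)
        if self.smooth:
            pix = convolve1d(lab, _BINOMIAL5, axis=0, mode="nearest")
            pix = convolve1d(pix, _BINOMIAL5, axis=1, mode="nearest")
        else:
            pix = lab
        means = np.stack([_surround_means(lab[..., c]) for c in range(3)], axis=-1)
        sq = ((means - pix) ** 2).sum(axis=-1)
        sal = sq if self.squared_distance else np.sqrt(sq)
        if sal.max() < 1e-9:  # flat image up to floating-point dust
            return np.zeros_like(sal)
        return minmax_normalize(sal, warn_constant=False)

    def transform_one(self, image) -> np.ndarray:
        sb = self.bottom_up(image)
        if self.center_bias is None:
            return sb
        cb = GaussianCenterBias(self.sigma_x_frac, self.sigma_y_frac)
        sc = cb.map_for_shape(sb.shape)
        spec = FusionSpec(self.center_bias, self.wc, self.weighted_extrema)
        return combine(sc, sb, spec)

    def transform(self, X):
        return [self.transform_one(img) for img in X]

    def __sklearn_is_fitted__(self):
        return True


def msss_saliency(image, smooth: bool = True) -> np.ndarray:
    """MSSS bottom-up saliency map, min-max normalized."""
    return MaximumSymmetricSurround(smooth=smooth).bottom_up(image)


def msss_cb_saliency(image, scheme: str = "convex", wc: float = 0.25,
                     weighted_extrema: bool = False, **kwargs) -> np.ndarray:
    """MSSS fused with the Gaussian center-bias map."""
    est = MaximumSymmetricSurround(center_bias=scheme, wc=wc,
                                   weighted_extrema=weighted_extrema, **kwargs)
    return est.transform_one(image)
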