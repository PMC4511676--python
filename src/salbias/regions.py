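"""Region segmentation, quantized Lab color histograms, spatial weights.

A :class:`RegionSet` bundles what segment-level contrast saliency needs:
the label map, per-region pixel counts and normalized centroids, and
per-region color histograms over a shared quantized palette represented in
CIE Lab.  Spatial interaction between regions is captured by
:class:`SpatialWeights`: Gaussian-decayed centroid distances, either raw
(``dhat``, which implicitly favors central regions) or row-normalized
(``dcheck``, the locally debiased form whose rows sum to one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage.segmentation import felzenszwalb

from ._utils import as_float_rgb
from .lattice import ImageLattice

__all__ = [
    "RegionSet",
    "SpatialWeights",
    "segment",
    "build_region_set",
    "quantize_colors",
    "region_histograms",
    "color_distance",
    "spatial_weights",
]


def segment(image, scale: float = 200.0, sigma: float = 0.8,
            min_size: int = 50) -> np.ndarray:
    """Partition an RGB image into connected regions (graph-based).

    Deterministic for fixed parameters; labels are relabeled to 0..K-1.
    A degenerate single-region output is allowed but flagged with a
    warning.
    """
    img = as_float_rgb(image)
    if min(img.shape[:2]) < 8:
        raise ValueError("image sides must be at least 8 pixels")
    labels = felzenszwalb(img, scale=scale, sigma=sigma, min_size=min_size)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(img.shape[:2])
    if labels.max() == 0:
        warnings.warn("segmentation produced a single region")
    return labels


def quantize_colors(image, levels: int = 12, keep_mass: float = 0.95):
    """Quantize sRGB colors to a compact palette with Lab representatives.

    Each channel is quantized to ``levels`` uniform bins (bin-center
    representatives).  The most frequent quantized colors that jointly
    cover at least ``keep_mass`` of the pixels are kept; every remaining
    pixel is reassigned to the perceptually nearest kept color (Euclidean
    distance in Lab).

    Returns
    -------
    index_map : (M, N) int array of palette indices per pixel
    palette_lab : (P, 3) Lab colors of the palette entries
    """
    img = as_float_rgb(image)
    bins = np.minimum((img * levels).astype(int), levels - 1)
    codes = (bins[..., 0] * levels + bins[..., 1]) * levels + bins[..., 2]
    uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
    order = np.argsort(counts)[::-1]
    cum = np.cumsum(counts[order]) / counts.sum()
    n_keep = int(np.searchsorted(cum, keep_mass) + 1)
    kept = order[:n_keep]

    # bin-center sRGB -> Lab for every occurring color
    rgb = np.stack(
        [(uniq // (levels * levels)) % levels, (uniq // levels) % levels, uniq % levels],
        axis=1,
    )
    rgb = (rgb + 0.5) / levels
    lab = skcolor.rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)

    remap = np.empty(uniq.size, dtype=int)
    remap[kept] = np.arange(n_keep)
    dropped = np.setdiff1d(np.arange(uniq.size), kept, assume_unique=False)
    if dropped.size:
        d = np.linalg.norm(lab[dropped, None, :] - lab[kept, :], axis=2)
        remap[dropped] = np.argmin(d, axis=1)
    index_map = remap[inverse].reshape(img.shape[:2])
    return index_map, lab[kept]


def region_histograms(labels: np.ndarray, index_map: np.ndarray,
                      n_palette: int) -> np.ndarray:
    """Per-region frequentist color probabilities; each row sums to 1."""
    if labels.shape != index_map.shape:
        raise ValueError("label map and color index map must share a shape")
    k = int(labels.max()) + 1
    flat = labels.ravel() * n_palette + index_map.ravel()
    counts = np.bincount(flat, minlength=k * n_palette).reshape(k, n_palette)
    return counts / counts.sum(axis=1, keepdims=True)


def color_distance(h1, h2, palette_lab) -> float:
    """Histogram contrast: expected Lab distance between random colors.

    ``sum_i sum_j f1(i) f2(j) ||lab_i - lab_j||`` over a shared palette.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    pal = np.asarray(palette_lab, dtype=float)
    d = np.linalg.norm(pal[:, None, :] - pal[None, :, :], axis=2)
    return float(h1 @ d @ h2)


@dataclass
class RegionSet:
    """Segmentation plus the per-region features contrast saliency uses."""

    labels: np.ndarray = field(repr=False)
    sizes: np.ndarray
    centroids: np.ndarray
    histograms: np.ndarray = field(repr=False)
    palette_lab: np.ndarray = field(repr=False)

    @property
    def n_regions(self) -> int:
        return int(self.sizes.size)

    def contrast_matrix(self) -> np.ndarray:
        """K x K matrix of pairwise histogram color distances."""
        pal = self.palette_lab
        d = np.linalg.norm(pal[:, None, :] - pal[None, :, :], axis=2)
        return self.histograms @ d @ self.histograms.T


def build_region_set(image, labels: np.ndarray | None = None,
                     levels: int = 12, keep_mass: float = 0.95,
                     **seg_params) -> RegionSet:
    """Segment (unless ``labels`` is given) and assemble a :class:`RegionSet`."""
    img = as_float_rgb(image)
    if labels is None:
        labels = segment(img, **seg_params)
    labels = np.asarray(labels)
    if labels.shape != img.shape[:2]:
        raise ValueError("label map shape must match the image")
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(uniq.size)):
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(img.shape[:2])
    k = int(labels.max()) + 1
    sizes = np.bincount(labels.ravel(), minlength=k)

    lattice = ImageLattice(*labels.shape)
    ii, jj = np.indices(labels.shape)
    x, y = lattice.pixel_center(ii, jj)
    cx = np.bincount(labels.ravel(), weights=x.ravel(), minlength=k) / sizes
    cy = np.bincount(labels.ravel(), weights=y.ravel(), minlength=k) / sizes

    index_map, palette = quantize_colors(img, levels=levels, keep_mass=keep_mass)
    hist = region_histograms(labels, index_map, palette.shape[0])
    return RegionSet(labels, sizes, np.column_stack([cx, cy]), hist, palette)


@dataclass
class SpatialWeights:
    """Pairwise centroid distances with biased and debiased Gaussian weights."""

    ds: np.ndarray = field(repr=False)
    dhat: np.ndarray = field(repr=False)
    dcheck: np.ndarray | None = field(repr=False)
    sigma_s2: float


def spatial_weights(centroids, sigma_s2: float = 0.4,
                    squared: bool = False) -> SpatialWeights:
    """Gaussian spatial weights between region centroids.

    ``dhat = exp(-ds / sigma_s2)`` on Euclidean distances in normalized
    coordinates (``exp(-ds**2 / sigma_s2)`` when ``squared``); ``dcheck``
    row-normalizes ``dhat`` over the other regions so each row sums to 1,
    removing the implicit advantage of centrally placed regions whose raw
    weight sums are larger.  ``dcheck`` is None for a single region.
    """
    if sigma_s2 <= 0:
        raise ValueError("sigma_s2 must be positive")
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("centroids must be (K, 2)")
    diff = c[:, None, :] - c[None, :, :]
    ds = np.linalg.norm(diff, axis=2)
    dhat = np.exp(-(ds**2 if squared else ds) / sigma_s2)
    k = c.shape[0]
    if k < 2:
        warnings.warn("single region: debiased weights undefined")
        return SpatialWeights(ds, dhat, None, sigma_s2)
    off = dhat.copy()
    np.fill_diagonal(off, 0.0)
    dcheck = off / off.sum(axis=1, keepdims=True)
    return SpatialWeights(ds, dhat, dcheck, sigma_s2)
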