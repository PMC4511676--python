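"""Synthetic scene generator with the polar centroid model built in.

Scenes emulate the structure of web salient-object photographs: one
clearly colored object on a contrasting background, its centroid placed
about the image center with a uniformly distributed polar angle and a
half-Gaussian radius (the "photographer's center bias"), occasional border
truncation, mild pixel noise, and optionally a few small off-center
distractor blobs that are *not* part of the ground truth.  A "no-bias"
preset draws centroids uniformly instead, emulating surveillance- or
robot-camera data with no compositional bias.

The default radial scale ``sigma_r = 0.211`` makes the per-axis Cartesian
centroid variance ``sigma_r^2 / 2 ~= 0.0223`` (normalized units), matching
the spread measured on web-photo corpora.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor

__all__ = ["SceneSpec", "sample_centroid", "render_scene", "make_dataset"]

DEFAULT_SIGMA_R = 0.211


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic salient-object scene family.

    Units: image size in pixels; colors in CIE Lab; ``min_delta_e`` the
    minimum Lab distance between object and background; area fractions
    relative to the image area; ``sigma_r`` the half-Gaussian radial scale
    and ``noise_sigma`` the per-channel sRGB noise standard deviation,
    both in normalized units.
    """

    height: int = 120
    width: int = 160
    sigma_r: float = DEFAULT_SIGMA_R
    centroid_model: str = "center_biased"  # or "uniform" (the no-bias preset)
    shape: str = "ellipse"  # or "rectangle"
    area_fraction: tuple[float, float] = (0.05, 0.20)
    min_delta_e: float = 40.0
    noise_sigma: float = 0.01
    n_distractors: int = 3
    distractor_area_fraction: tuple[float, float] = (0.01, 0.04)
    distractor_min_radius: float = 0.3
    n_background_bands: int = 2
    band_delta_e: float = 15.0

    def __post_init__(self):
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be positive")
        if not 0 < self.area_fraction[0] <= self.area_fraction[1] <= 0.5:
            raise ValueError("area fraction range must lie in (0, 0.5]")
        if self.min_delta_e <= 0:
            raise ValueError("min_delta_e must be positive")
        if self.centroid_model not in ("center_biased", "uniform"):
            raise ValueError("centroid_model must be 'center_biased' or 'uniform'")
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError("shape must be 'ellipse' or 'rectangle'")
        if self.n_background_bands < 1:
            raise ValueError("need at least one background band")


def sample_centroid(sigma_r: float = DEFAULT_SIGMA_R, rng=None,
                    model: str = "center_biased") -> tuple[float, float, float, float]:
    """Draw one centroid from the polar spatial prior.

    Angle ~ Uniform[-pi, pi], radius ~ |Normal(0, sigma_r)|, about the
    pole (0.5, 0.5); the point is clipped to the unit square.  Returns
    ``(x, y, r, theta)``.  ``model="uniform"`` instead draws the point
    uniformly over [0.1, 0.9]^2 (no-bias preset).
    """
    rng = np.random.default_rng(rng)
    if model == "uniform":
        x, y = rng.uniform(0.1, 0.9, size=2)
        r = math.hypot(x - 0.5, y - 0.5)
        theta = math.atan2(y - 0.5, x - 0.5) if r > 0 else 0.0
        return float(x), float(y), float(r), float(theta)
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    theta = rng.uniform(-np.pi, np.pi)
    r = abs(rng.normal(0.0, sigma_r))
    x = float(np.clip(0.5 + r * math.cos(theta), 0.0, 1.0))
    y = float(np.clip(0.5 + r * math.sin(theta), 0.0, 1.0))
    return x, y, float(r), float(theta)


def _lab_to_rgb(lab) -> np.ndarray:
    return np.clip(skcolor.lab2rgb(np.asarray(lab, dtype=float).reshape(1, 1, 3)), 0, 1)[0, 0]


def _random_lab(rng, l_range=(20.0, 80.0), ab_range=(-60.0, 60.0)) -> np.ndarray:
    return np.array([rng.uniform(*l_range), rng.uniform(*ab_range), rng.uniform(*ab_range)])


def _contrasting_lab(rng, reference: np.ndarray, min_delta_e: float,
                     max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        cand = _random_lab(rng)
        if np.linalg.norm(cand - reference) >= min_delta_e:
            return cand
    raise RuntimeError("could not find a sufficiently contrasting color")


def _blob_mask(shape_kind: str, M: int, N: int, cx: float, cy: float,
               area_px: float, aspect: float, angle: float) -> np.ndarray:
    """Rasterize an ellipse/rectangle of the given area on the pixel grid."""
    jj, ii = np.meshgrid(np.arange(N), np.arange(M))
    x = (jj + 0.5) / N - cx
    y = (ii + 0.5) / M - cy
    # rotate into the blob frame (normalized coordinates, y-down)
    u = (x * math.cos(angle) + y * math.sin(angle))
    v = (-x * math.sin(angle) + y * math.cos(angle))
    area_norm = area_px / (M * N)
    if shape_kind == "ellipse":
        b = math.sqrt(area_norm / (math.pi * aspect))
        a = aspect * b
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    b = math.sqrt(area_norm / aspect)
    a = aspect * b
    return (np.abs(u) <= a / 2) & (np.abs(v) <= b / 2)


def render_scene(spec: SceneSpec, centroid: tuple[float, float] | None = None,
                 rng=None, max_retries: int = 20):
    """Render one (image, mask) pair.

    The salient object is rasterized at ``centroid`` (drawn from the
    spec's centroid model when omitted); objects may be truncated by the
    image borders, in which case the mask centroid shifts inward, exactly
    as for real border-touching objects.  Distractor blobs never overlap
    the object and are excluded from the mask.  Returns
    ``(image, mask, info)`` with the image as float RGB in [0, 1] and
    ``info`` a dict of the drawn parameters.
    """
    rng = np.random.default_rng(rng)
    M, N = spec.height, spec.width
    if centroid is None:
        cx, cy, r, theta = sample_centroid(spec.sigma_r, rng, spec.centroid_model)
    else:
        cx, cy = float(centroid[0]), float(centroid[1])
        r = math.hypot(cx - 0.5, cy - 0.5)
        theta = math.atan2(cy - 0.5, cx - 0.5) if r > 0 else 0.0

    # Background: one or more color bands (sky/ground-style composition),
    # so that segmentation yields background regions with off-center
    # centroids, as in real photographs.
    base_lab = _random_lab(rng, l_range=(25.0, 75.0), ab_range=(-30.0, 30.0))
    band_labs = [base_lab]
    for _ in range(spec.n_background_bands - 1):
        jitter = rng.normal(0.0, 1.0, 3)
        jitter *= spec.band_delta_e / np.linalg.norm(jitter)
        band_labs.append(band_labs[-1] + jitter)
    bg_lab = base_lab

    obj_lab = None
    for _ in range(200):
        cand = _random_lab(rng)
        if all(np.linalg.norm(cand - b) >= spec.min_delta_e for b in band_labs):
            obj_lab = cand
            break
    if obj_lab is None:
        raise RuntimeError("could not find a sufficiently contrasting object color")

    mask = None
    for _ in range(max_retries):
        frac = rng.uniform(*spec.area_fraction)
        aspect = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
        angle = rng.uniform(0, math.pi)
        cand = _blob_mask(spec.shape, M, N, cx, cy, frac * M * N, aspect, angle)
        if cand.any():
            mask = cand
            break
    if mask is None:
        raise RuntimeError("object was fully clipped away; centroid too far outside")

    image = np.empty((M, N, 3))
    image[:] = _lab_to_rgb(bg_lab)
    if len(band_labs) > 1:
        horizontal = bool(rng.random() < 0.5)
        extent = M if horizontal else N
        cuts = np.sort(rng.uniform(0.3, 0.7, len(band_labs) - 1)) * extent
        edges = np.concatenate([[0], cuts.astype(int), [extent]])
        for lab, lo, hi in zip(band_labs, edges[:-1], edges[1:]):
            if horizontal:
                image[lo:hi, :] = _lab_to_rgb(lab)
            else:
                image[:, lo:hi] = _lab_to_rgb(lab)
    image[mask] = _lab_to_rgb(obj_lab)

    for _ in range(spec.n_distractors):
        for _ in range(max_retries):
            dx, dy = rng.uniform(0.1, 0.9, size=2)
            # distractors are peripheral clutter: the scene has exactly one
            # centrally composed subject, so clutter keeps clear of the center
            if math.hypot(dx - 0.5, dy - 0.5) < spec.distractor_min_radius:
                continue
            dfrac = rng.uniform(*spec.distractor_area_fraction)
            daspect = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
            dangle = rng.uniform(0, math.pi)
            dmask = _blob_mask(spec.shape, M, N, dx, dy, dfrac * M * N, daspect, dangle)
            if dmask.any() and not (dmask & mask).any():
                dlab = _contrasting_lab(rng, bg_lab, 30.0)
                image[dmask] = _lab_to_rgb(dlab)
                break

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
        image = np.clip(image, 0.0, 1.0)

    info = {"cx": cx, "cy": cy, "r": r, "theta": theta,
            "area_fraction": float(mask.mean())}
    return image, mask, info


def make_dataset(n: int, spec: SceneSpec | None = None, seed=0):
    """Generate ``n`` independent scenes plus a manifest.

    Returns ``(images, masks, manifest)`` where the manifest is a
    DataFrame with one row per scene (index, true centroid, polar form,
    realized area fraction, child seed).  Regeneration from the same
    ``(spec, seed)`` is bit-identical.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = spec or SceneSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    images, masks, rows = [], [], []
    for i, child in enumerate(children):
        img, mask, info = render_scene(spec, rng=np.random.default_rng(child))
        images.append(img)
        masks.append(mask)
        rows.append({"index": i, **info, "seed": int(child.generate_state(1)[0] % (2**31))})
    return images, masks, pd.DataFrame(rows)


def spec_to_dict(spec: SceneSpec) -> dict:
    """Flat dict form of a spec (manifest/config serialization)."""
    d = asdict(spec)
    d["area_fraction_lo"], d["area_fraction_hi"] = d.pop("area_fraction")
    lo, hi = d.pop("distractor_area_fraction")
    d["distractor_area_fraction_lo"], d["distractor_area_fraction_hi"] = lo, hi
    return d
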