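"""Probability-plot correlation coefficient (PPCC) goodness-of-fit testing.

The PPCC is the Pearson correlation between the order statistics of a sample
and the quantiles of a hypothesised model evaluated at plotting positions.
Because correlation is invariant under positive affine maps, the statistic
measures distributional *shape* agreement without requiring location or
scale parameters — convenient for testing whether salient-object centroid
angles are uniform on [-pi, pi] and radii half-Gaussian, where the radial
scale is unknown.  Comparing the PPCC against tabulated critical values
turns the plot into a test closely related to Shapiro-Wilk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lattice as _lat
from ._ppcc_tables import lookup as _lookup_critical

__all__ = [
    "PpccResult",
    "CentroidReport",
    "plotting_positions",
    "model_quantile_fn",
    "ppcc",
    "ppcc_fit_test",
    "correlation_t_test",
    "analyze_centroids",
    "analyze_points",
]

MODELS = ("uniform", "half_gaussian", "gaussian")
_MODEL_KEY = {"uniform": "uniform", "half_gaussian": "half_gaussian", "gaussian": "normal"}


@dataclass(frozen=True)
class PpccResult:
    """Outcome of a PPCC goodness-of-fit test."""

    ppcc: float
    n: int
    critical_value: float | None = None
    alpha: float | None = None
    reject_fit: bool | None = None
    p_no_correlation: float | None = None
    model: str | None = None


def plotting_positions(n: int, kind: str = "midpoint") -> np.ndarray:
    """Probabilities at which model quantiles are evaluated.

    ``"midpoint"`` gives ``(i - 0.5)/n``; ``"filliben"`` gives Filliben's
    order-statistic medians.  The two differ negligibly for n in the
    hundreds.
    """
    i = np.arange(1, n + 1, dtype=float)
    if kind == "midpoint":
        return (i - 0.5) / n
    if kind == "filliben":
        p = (i - 0.3175) / (n + 0.365)
        p[0] = 1 - 0.5 ** (1 / n)
        p[-1] = 0.5 ** (1 / n)
        return p
    raise ValueError(f"unknown plotting-position kind {kind!r}")


def model_quantile_fn(model: str) -> Callable[[np.ndarray], np.ndarray]:
    """Inverse CDF of a named standard model."""
    if model == "uniform":
        return lambda p: -np.pi + 2 * np.pi * np.asarray(p, dtype=float)
    if model == "half_gaussian":
        return stats.halfnorm.ppf
    if model == "gaussian":
        return stats.norm.ppf
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def ppcc(
    samples: Sequence[float],
    quantile_fn: Callable[[np.ndarray], np.ndarray],
    positions: str = "midpoint",
) -> float:
    """Correlation between sorted samples and model quantiles.

    Location-scale invariant: ``ppcc(a*x + b, q) == ppcc(x, q)`` for a > 0.

    Raises
    ------
    ValueError
        If fewer than 3 samples are given or the sample is constant
        (correlation undefined).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("PPCC needs at least 3 samples")
    q = np.asarray(quantile_fn(plotting_positions(n, positions)), dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("quantile function returned non-finite values")
    xc = x - x.mean()
    qc = q - q.mean()
    sx = float(np.sqrt(xc @ xc))
    sq = float(np.sqrt(qc @ qc))
    if sx == 0.0:
        raise ValueError("constant sample: PPCC undefined")
    if sq == 0.0:
        raise ValueError("constant model quantiles: PPCC undefined")
    return float(np.clip((xc @ qc) / (sx * sq), -1.0, 1.0))


def correlation_t_test(r: float, n: int) -> float:
    """Two-sided p-value for zero correlation given Pearson r on n pairs.

    Uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom;
    |r| = 1 returns the limit p = 0.
    """
    if n <= 2:
        raise ValueError("need n > 2")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def ppcc_fit_test(
    samples: Sequence[float],
    model: str,
    alpha: float = 0.05,
    positions: str = "midpoint",
    critical_source: str = "auto",
) -> PpccResult:
    """PPCC test of whether ``samples`` follow ``model`` up to location/scale.

    The fit hypothesis is rejected when the PPCC falls below the critical
    value tabulated for (model, n, alpha); see :mod:`salbias._ppcc_tables`
    for the available sources.  ``p_no_correlation`` is the companion
    t-test of zero correlation between the paired quantiles.
    """
    r = ppcc(samples, model_quantile_fn(model), positions)
    n = len(samples)
    crit = _lookup_critical(_MODEL_KEY[model], n, alpha, critical_source)
    return PpccResult(
        ppcc=r,
        n=n,
        critical_value=crit,
        alpha=alpha,
        reject_fit=bool(r < crit),
        p_no_correlation=correlation_t_test(r, n),
        model=model,
    )


@dataclass
class CentroidReport:
    """Spatial summary and distributional tests for a set of centroids."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int
    angle_test: PpccResult
    radius_test: PpccResult
    folded_radius_test: PpccResult
    degenerate: bool
    qq_angle: pd.DataFrame = field(repr=False)
    qq_radius: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One-row summary table (CSV-friendly)."""
        return pd.DataFrame(
            {
                "n": [self.n],
                "mean_x": [self.mean[0]],
                "mean_y": [self.mean[1]],
                "var_x": [self.covariance[0, 0]],
                "var_y": [self.covariance[1, 1]],
                "cov_xy": [self.covariance[0, 1]],
                "angle_ppcc": [self.angle_test.ppcc],
                "angle_reject": [self.angle_test.reject_fit],
                "radius_ppcc": [self.radius_test.ppcc],
                "radius_reject": [self.radius_test.reject_fit],
                "folded_radius_ppcc": [self.folded_radius_test.ppcc],
                "degenerate": [self.degenerate],
            }
        )


def _qq_frame(samples: np.ndarray, model: str, positions: str) -> pd.DataFrame:
    q = model_quantile_fn(model)(plotting_positions(samples.size, positions))
    return pd.DataFrame({"sample_q": np.sort(samples), "model_q": q})


def analyze_points(
    points,
    pole=_lat.CENTER,
    alpha: float = 0.05,
    positions: str = "midpoint",
    critical_source: str = "auto",
) -> CentroidReport:
    """Test the polar spatial-prior model on centroid locations.

    The model holds that, about the image center, centroid angles are
    uniform on [-pi, pi] and radii half-Gaussian.  The radius hypothesis is
    tested twice: radii against half-Gaussian quantiles, and angle-folded
    signed radii against full-Gaussian quantiles; the two PPCCs agree
    closely on data that follow the model.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of normalized (x, y)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 centroids")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    degenerate = bool(np.allclose(cov, 0.0))
    if degenerate:
        warnings.warn("all centroids coincide: covariance is zero, tests skipped")
        null = PpccResult(ppcc=float("nan"), n=pts.shape[0])
        empty = pd.DataFrame({"sample_q": [], "model_q": []})
        return CentroidReport(mean, np.atleast_2d(cov), pts.shape[0], null, null, null, True, empty, empty)

    polar = [_lat.to_polar(p, pole) for p in pts]
    radii = np.array([p.radius for p in polar])
    angles = np.array([p.angle for p in polar])
    folded = np.array([_lat.fold_polar(p).radius for p in polar])

    kw = dict(alpha=alpha, positions=positions, critical_source=critical_source)
    return CentroidReport(
        mean=mean,
        covariance=cov,
        n=pts.shape[0],
        angle_test=ppcc_fit_test(angles, "uniform", **kw),
        radius_test=ppcc_fit_test(radii, "half_gaussian", **kw),
        folded_radius_test=ppcc_fit_test(folded, "gaussian", **kw),
        degenerate=False,
        qq_angle=_qq_frame(angles, "uniform", positions),
        qq_radius=_qq_frame(radii, "half_gaussian", positions),
    )


def analyze_centroids(masks: Sequence, exclude_border_touching: bool = False,
                      **kwargs) -> CentroidReport:
    """:func:`analyze_points` applied to mask centroids.

    Each mask is a binary 2-D array with at least one foreground pixel;
    masks of differing resolutions are fine (coordinates are normalized).
    Border-truncated objects pull their centroid inward; by default they
    are kept (the radial model is one-sided, not truncated), but
    ``exclude_border_touching`` drops masks whose foreground touches the
    image border for sensitivity analysis.
    """
    if exclude_border_touching:
        masks = [
            m for m in masks
            if not (np.asarray(m)[0].any() or np.asarray(m)[-1].any()
                    or np.asarray(m)[:, 0].any() or np.asarray(m)[:, -1].any())
        ]
    if len(masks) < 3:
        raise ValueError("need at least 3 masks")
    pts = [_lat.mask_centroid(m) for m in masks]
    return analyze_points(pts, **kwargs)
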