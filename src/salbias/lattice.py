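"""Image lattice geometry: normalized coordinates, mask centroids, polar frames.

Pixel ``(row i, col j)`` of an ``M x N`` image maps to the normalized point
``((j + 0.5) / N, (i + 0.5) / M)`` in ``[0, 1] x [0, 1]`` with the y-axis
pointing down, so that centroids of symmetric masks are exact and images of
different resolutions live on a common unit square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageLattice",
    "PolarPoint",
    "FoldedPolarPoint",
    "mask_centroid",
    "to_polar",
    "polar_to_cartesian",
    "fold_polar",
    "unfold_polar",
]

CENTER = (0.5, 0.5)


@dataclass(frozen=True)
class ImageLattice:
    """An ``M x N`` pixel grid with its normalized coordinate convention."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("lattice must have at least one pixel per side")

    def pixel_center(self, i, j):
        """Normalized (x, y) of the center of pixel (row i, col j)."""
        return (np.asarray(j) + 0.5) / self.width, (np.asarray(i) + 0.5) / self.height


@dataclass(frozen=True)
class PolarPoint:
    """Polar representation about a pole, angle in [-pi, pi], y-down."""

    radius: float
    angle: float
    pole: tuple[float, float] = CENTER


@dataclass(frozen=True)
class FoldedPolarPoint:
    """Half-plane polar form: angle folded into [0, pi], radius signed."""

    radius: float
    angle: float
    pole: tuple[float, float] = CENTER


def mask_centroid(mask, lattice: ImageLattice | None = None) -> tuple[float, float]:
    """Centroid of a binary mask in normalized coordinates.

    Parameters
    ----------
    mask : 2-D array-like
        Non-zero entries are foreground.
    lattice : ImageLattice, optional
        Defaults to the lattice implied by ``mask.shape``.

    Returns
    -------
    (x, y) : tuple of float
        Mean of the normalized pixel-center coordinates of the foreground.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if lattice is None:
        lattice = ImageLattice(*mask.shape)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise ValueError("mask has no foreground pixels")
    x, y = lattice.pixel_center(ii, jj)
    return float(np.mean(x)), float(np.mean(y))


def to_polar(point, pole=CENTER) -> PolarPoint:
    """Polar coordinates of a normalized point about a pole.

    The angle is ``atan2(y - pole_y, x - pole_x)``; with the y-down image
    convention a point below the pole has angle ``+pi/2``.  A zero radius
    yields angle 0 by convention.
    """
    dx = point[0] - pole[0]
    dy = point[1] - pole[1]
    r = math.hypot(dx, dy)
    theta = math.atan2(dy, dx) if r > 0 else 0.0
    return PolarPoint(r, theta, tuple(pole))


def polar_to_cartesian(p: PolarPoint | FoldedPolarPoint) -> tuple[float, float]:
    """Inverse of :func:`to_polar`; also accepts folded points."""
    return (
        p.pole[0] + p.radius * math.cos(p.angle),
        p.pole[1] + p.radius * math.sin(p.angle),
    )


def fold_polar(p: PolarPoint) -> FoldedPolarPoint:
    """Fold a polar point into positive angles ``[0, pi]`` and signed radii.

    Points with negative angle are re-expressed through the antipodal
    direction: ``(r, theta) -> (-r, theta + pi)``.  The represented Cartesian
    point is unchanged, which lets a one-sided radial sample be compared
    against a full (two-sided) Gaussian model.
    """
    if not -math.pi <= p.angle <= math.pi:
        raise ValueError("angle must lie in [-pi, pi]")
    if p.angle >= 0:
        return FoldedPolarPoint(p.radius, p.angle, p.pole)
    return FoldedPolarPoint(-p.radius, p.angle + math.pi, p.pole)


def unfold_polar(p: FoldedPolarPoint) -> PolarPoint:
    """Undo :func:`fold_polar` (canonical angle-in-[-pi,pi] form)."""
    if p.radius >= 0:
        return PolarPoint(p.radius, p.angle, p.pole)
    return PolarPoint(-p.radius, p.angle - math.pi, p.pole)
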