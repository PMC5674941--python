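"""Radius estimation, minimal enclosing circles, and circle-restricted
intensity statistics.

The colony and its core are each summarized by two geometric quantities
derived from the annotated boundary points:

* the *average radius* — the mean Euclidean distance of the boundary points
  from the image center (the reference point for radius measurements);
* the *minimal bounding circle* — the smallest circle containing all the
  points, which defines the region over which mean fluorescence intensity is
  computed.

The minimal circle is computed exactly with Welzl's randomized incremental
algorithm, not approximated; its center generally differs from the image
center, and both are reported.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from biofilmq.errors import ValidationError

_EPS = 1e-9


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates: center (cx, cy) and radius r >= 0."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValidationError(f"circle radius must be >= 0, got {self.r}")

    def contains(self, x: float, y: float, tol: float = _EPS) -> bool:
        return math.hypot(x - self.cx, y - self.cy) <= self.r + tol


@dataclass
class RegionMeasurement:
    """Per-region quantities for one image: radius, bounding circle, intensity."""

    avg_radius: float
    bounding_circle: Circle
    mean_intensity: float
    pixel_count: int


def average_radius(points: np.ndarray, center: tuple[float, float]) -> float:
    """Mean Euclidean distance of boundary points from a reference center."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise ValidationError("average_radius needs at least one point")
    cx, cy = center
    return float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).mean())


def _circle_two(p: np.ndarray, q: np.ndarray) -> Circle:
    cx, cy = (p + q) / 2.0
    return Circle(float(cx), float(cy), float(np.hypot(*(p - q)) / 2.0))


def _circumcircle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> Circle | None:
    """Circumscribed circle of a triangle; None when the points are collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return Circle(float(ux), float(uy), float(math.hypot(ax - ux, ay - uy)))


def _trivial_circle(boundary: list[np.ndarray]) -> Circle:
    if not boundary:
        return Circle(0.0, 0.0, 0.0)
    if len(boundary) == 1:
        return Circle(float(boundary[0][0]), float(boundary[0][1]), 0.0)
    if len(boundary) == 2:
        return _circle_two(boundary[0], boundary[1])
    a, b, c = boundary
    # A pair may already enclose the third point (obtuse triangle).
    for p, q, other in ((a, b, c), (a, c, b), (b, c, a)):
        circ = _circle_two(p, q)
        if circ.contains(other[0], other[1]):
            return circ
    circ = _circumcircle(a, b, c)
    if circ is None:  # collinear: the widest pair encloses all three
        pairs = [(a, b), (a, c), (b, c)]
        return max((_circle_two(p, q) for p, q in pairs), key=lambda c_: c_.r)
    return circ


def minimal_bounding_circle(points: np.ndarray, seed: int = 0) -> Circle:
    """Smallest circle containing all the points (Welzl's algorithm).

    Duplicate points are deduplicated internally. The result is exact up to
    floating-point arithmetic: every input point lies within ``r + 1e-9`` of
    the center, and at least two points lie on the boundary unless n == 1.
    The ``seed`` only fixes the internal processing order; the output is the
    same circle for any seed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise ValidationError("minimal_bounding_circle needs at least one point")
    uniq = np.unique(pts, axis=0)
    order = list(range(len(uniq)))
    random.Random(seed).shuffle(order)
    shuffled = [uniq[i] for i in order]

    circle = Circle(float(shuffled[0][0]), float(shuffled[0][1]), 0.0)
    for i, p in enumerate(shuffled[1:], start=1):
        if circle.contains(p[0], p[1]):
            continue
        circle = Circle(float(p[0]), float(p[1]), 0.0)
        for j in range(i):
            q = shuffled[j]
            if circle.contains(q[0], q[1]):
                continue
            circle = _circle_two(p, q)
            for k in range(j):
                s = shuffled[k]
                if circle.contains(s[0], s[1]):
                    continue
                circle = _trivial_circle([p, q, s])
    return circle


def mean_intensity_in_circle(img: np.ndarray, circle: Circle) -> tuple[float, int]:
    """Mean grayscale intensity over the pixels inside a circle.

    A pixel belongs to the circle iff its center satisfies
    ``(x - cx)^2 + (y - cy)^2 <= r^2`` (no partial weighting); the region is
    clipped to the image bounds.

    Returns
    -------
    (mean, pixel_count)
    """
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale array, got shape {gray.shape}")
    h, w = gray.shape
    x0 = max(0, int(math.floor(circle.cx - circle.r)))
    x1 = min(w - 1, int(math.ceil(circle.cx + circle.r)))
    y0 = max(0, int(math.floor(circle.cy - circle.r)))
    y1 = min(h - 1, int(math.ceil(circle.cy + circle.r)))
    if x0 > x1 or y0 > y1:
        raise ValidationError(
            f"circle (cx={circle.cx}, cy={circle.cy}, r={circle.r}) lies entirely outside "
            f"the {w}x{h} image"
        )
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask = (xs - circle.cx) ** 2 + (ys - circle.cy) ** 2 <= circle.r**2 + _EPS
    count = int(mask.sum())
    if count == 0:
        raise ValidationError(
            f"circle (cx={circle.cx}, cy={circle.cy}, r={circle.r}) contains no pixel center "
            f"inside the {w}x{h} image"
        )
    return float(gray[y0 : y1 + 1, x0 : x1 + 1][mask].mean()), count


def measure_region(
    img: np.ndarray,
    points: np.ndarray,
    center: tuple[float, float],
) -> RegionMeasurement:
    """Bundle the radius and intensity measurements for one boundary-point set.

    ``avg_radius`` is measured from ``center`` (conventionally the image
    center); the intensity is averaged inside the minimal bounding circle of
    the points, whose own center may differ.
    """
    circle = minimal_bounding_circle(points)
    mean, count = mean_intensity_in_circle(img, circle)
    return RegionMeasurement(
        avg_radius=average_radius(points, center),
        bounding_circle=circle,
        mean_intensity=mean,
        pixel_count=count,
    )
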