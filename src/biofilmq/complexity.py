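"""Intensity-based complexity scoring of the colony core.

The core's three-dimensional channel structure shows up in a top-down
fluorescence image as thin high-intensity bands crisscrossing a darker
background. To quantify it, the image is reduced to a one-dimensional signal
by reading grayscale intensities along an outward Archimedean spiral starting
at the image center (2000 unit-arc-length samples by default, covering a
central region of the core). The signal is then scored by two variables over
consecutive overlapping windows of 20 samples (stride 1):

* **amplitude** — the mean per-window ``max - min``, capturing the magnitude
  of crossovers between bright young bands and dark aged layers;
* **frequency** — the mean per-window variance (population, i.e. window-length
  denominator), capturing how often those crossovers occur.

Smooth, uniform cores score near (0, 0); mature wrinkled cores score high in
both coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import map_coordinates

from biofilmq.errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 2000
DEFAULT_PITCH = 4.0
DEFAULT_WINDOW = 20


@dataclass
class SpiralPath:
    """An outward Archimedean spiral sampled at ~unit arc-length steps.

    ``samples`` is an (n, 2) array of continuous (x, y) positions starting at
    ``center``; ``radii`` holds each sample's distance from the center
    (non-decreasing along the path). ``pitch`` is the radial gain per full
    360-degree turn, in pixels.
    """

    samples: np.ndarray
    center: tuple[float, float]
    pitch: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.samples[:, 0] - self.center[0], self.samples[:, 1] - self.center[1])


@dataclass(frozen=True)
class ComplexityScore:
    """(amplitude, frequency) pair for one image, with the window used."""

    amplitude: float
    frequency: float
    window: int = DEFAULT_WINDOW


def spiral_path(
    center: tuple[float, float],
    n_samples: int = DEFAULT_N_SAMPLES,
    pitch: float = DEFAULT_PITCH,
) -> SpiralPath:
    """Trace an Archimedean spiral ``r = pitch * theta / 2pi`` from ``center``.

    The path is sampled at (approximately) unit arc-length steps: each step
    advances the angle by an amount iteratively corrected so that the chord to
    the previous sample is 1 px (within 1e-3). Consecutive spacing therefore
    stays within [0.9, 1.1] px and the radius is non-decreasing.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    if pitch <= 0:
        raise ValidationError(f"pitch must be > 0, got {pitch}")
    a = pitch / (2.0 * math.pi)
    cx, cy = center
    pts = np.empty((n_samples, 2), dtype=np.float64)
    pts[0] = (cx, cy)
    theta = 0.0
    step = 1.0
    for i in range(1, n_samples):
        r = a * theta
        dtheta = step / max(math.hypot(r, a), 1e-12)
        px, py = pts[i - 1]
        for _ in range(12):
            tn = theta + dtheta
            rn = a * tn
            x = cx + rn * math.cos(tn)
            y = cy + rn * math.sin(tn)
            d = math.hypot(x - px, y - py)
            if abs(d - step) < 1e-3:
                break
            dtheta *= step / d
        theta = tn
        pts[i] = (x, y)
    return SpiralPath(samples=pts, center=(cx, cy), pitch=pitch)


def spiral_max_radius(n_samples: int, pitch: float) -> float:
    """Arc-length prediction of the spiral's final radius.

    For an Archimedean spiral with radial gain ``a = pitch / 2pi`` the arc
    length grows as ``s ~ a * theta^2 / 2``, so ``n_samples`` unit steps reach
    ``r = sqrt(2 * n_samples * a)``.
    """
    return math.sqrt(2.0 * n_samples * pitch / (2.0 * math.pi))


def sample_signal(img: np.ndarray, path: SpiralPath, interpolation: str = "bilinear") -> np.ndarray:
    """Read the grayscale field along the spiral path.

    Values are interpolated bilinearly at the continuous sample positions
    (nearest-neighbor available via ``interpolation="nearest"``). All samples
    must fall inside the image.
    """
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale array, got shape {gray.shape}")
    h, w = gray.shape
    xs = path.samples[:, 0]
    ys = path.samples[:, 1]
    outside = (xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)
    if outside.any():
        first = int(np.argmax(outside))
        raise ValidationError(
            f"spiral sample {first} at ({xs[first]:.2f}, {ys[first]:.2f}) falls outside "
            f"the {w}x{h} image"
        )
    if interpolation not in ("bilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "bilinear" else 0
    return map_coordinates(gray, np.vstack([ys, xs]), order=order, mode="nearest")


def _windows(signal: np.ndarray, window: int) -> np.ndarray:
    values = np.asarray(signal, dtype=np.float64)
    if values.ndim != 1:
        raise ValidationError(f"expected a 1-D signal, got shape {values.shape}")
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if len(values) < window:
        raise ValidationError(f"signal length {len(values)} is shorter than the window {window}")
    return sliding_window_view(values, window)


def windowed_amplitude(signal: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    """Mean per-window (max - min) over all stride-1 windows of the signal."""
    w = _windows(signal, window)
    return float(np.mean(w.max(axis=1) - w.min(axis=1)))


def windowed_frequency(signal: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    """Mean per-window population variance over all stride-1 windows."""
    w = _windows(signal, window)
    return float(np.mean(w.var(axis=1)))


def complexity_score(
    img: np.ndarray,
    center: tuple[float, float],
    n_samples: int = DEFAULT_N_SAMPLES,
    pitch: float = DEFAULT_PITCH,
    window: int = DEFAULT_WINDOW,
    core_radius: float | None = None,
    interpolation: str = "bilinear",
) -> ComplexityScore:
    """Spiral-sample the core and score amplitude and frequency.

    If ``core_radius`` (the annotated core bounding-circle radius) is given
    and the spiral extends beyond it, a warning is logged: the path is then no
    longer confined to the core region the score is meant to characterize.
    """
    path = spiral_path(center, n_samples=n_samples, pitch=pitch)
    max_r = float(path.radii.max()) if path.n_samples else 0.0
    if core_radius is not None and max_r > core_radius:
        logger.warning(
            "spiral max radius %.1f px exceeds the core bounding-circle radius %.1f px",
            max_r,
            core_radius,
        )
    signal = sample_signal(img, path, interpolation=interpolation)
    return ComplexityScore(
        amplitude=windowed_amplitude(signal, window),
        frequency=windowed_frequency(signal, window),
        window=window,
    )


def max_complexity(scores: list[ComplexityScore], joint: bool = False) -> tuple[float, float]:
    """Maximal attained (amplitude, frequency) over a colony's timepoints.

    By default maxima are taken coordinate-wise (they may occur on different
    days); ``joint=True`` instead returns the single day whose score pair has
    the largest Euclidean norm.
    """
    if not scores:
        raise ValidationError("max_complexity needs at least one scored timepoint")
    if joint:
        best = max(scores, key=lambda s: math.hypot(s.amplitude, s.frequency))
        return (best.amplitude, best.frequency)
    return (max(s.amplitude for s in scores), max(s.frequency for s in scores))
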