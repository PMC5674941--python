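"""Independent brute-force oracles used to check the implementation.

These deliberately use the slowest, most literal formulation of each
quantity and share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_min_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive minimal enclosing circle over all point pairs and triples."""
    pts = [tuple(map(float, p)) for p in np.atleast_2d(points)]
    pts = sorted(set(pts))
    if len(pts) == 1:
        return (pts[0][0], pts[0][1], 0.0)

    def contains_all(cx: float, cy: float, r: float) -> bool:
        return all(math.hypot(x - cx, y - cy) <= r + 1e-9 for x, y in pts)

    candidates = []
    for (ax, ay), (bx, by) in itertools.combinations(pts, 2):
        cx, cy = (ax + bx) / 2, (ay + by) / 2
        candidates.append((cx, cy, math.hypot(ax - bx, ay - by) / 2))
    for (ax, ay), (bx, by), (cx_, cy_) in itertools.combinations(pts, 3):
        d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax**2 + ay**2) * (by - cy_) + (bx**2 + by**2) * (cy_ - ay) + (cx_**2 + cy_**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx_ - bx) + (bx**2 + by**2) * (ax - cx_) + (cx_**2 + cy_**2) * (bx - ax)) / d
        candidates.append((ux, uy, math.hypot(ax - ux, ay - uy)))
    best = min((c for c in candidates if contains_all(*c)), key=lambda c: c[2])
    return best


def naive_window_stats(signal: np.ndarray, window: int) -> tuple[float, float]:
    """Literal per-window loop for mean range and mean population variance."""
    values = list(map(float, signal))
    amps, variances = [], []
    for start in range(len(values) - window + 1):
        chunk = values[start : start + window]
        amps.append(max(chunk) - min(chunk))
        mean = sum(chunk) / window
        variances.append(sum((v - mean) ** 2 for v in chunk) / window)
    return (sum(amps) / len(amps), sum(variances) / len(variances))
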