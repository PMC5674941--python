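"""Image and annotation I/O.

Images are 8-bit PNGs, one per colony per day, all the same size within a
series and never normalized: measurements operate on the native 0-255 scale.
An RGB image is represented as an ``(H, W, 3)`` uint8 array; its grayscale
representation (the substrate of all intensity measurements) is the per-pixel
arithmetic mean of the three channels, kept real-valued. In that
representation strong GFP signal is bright and background is dark.

Boundary annotations are CSV files holding manually selected points on the
outer colony boundary and the inner core boundary (16 per region by default).
Coordinates are 0-based with x = column and y = row; pixel centers sit at
integer coordinates and the image center is ``((W-1)/2, (H-1)/2)``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from biofilmq.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_POINTS = 16


def image_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Center of an ``(H, W)`` image in (x, y) pixel coordinates."""
    h, w = shape[:2]
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG into an ``(H, W, 3)`` uint8 array.

    Grayscale PNGs are promoted to three identical channels; an alpha channel
    is dropped with a logged warning. No normalization or rescaling is
    applied.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If the file is not a readable 8-bit image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel of %s", path)
                im = im.convert("RGB" if im.mode in ("RGBA", "PA") else "L")
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
                return np.repeat(arr[:, :, None], 3, axis=2)
            if im.mode == "RGB":
                return np.asarray(im, dtype=np.uint8)
            raise FormatError(f"unsupported image mode {im.mode!r} (need 8-bit gray or RGB): {path}")
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale as the mean of the three channels.

    The result is real-valued (float64) on the 0-255 scale; no quantization
    is applied so downstream statistics see the exact channel average.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return arr.astype(np.float64).mean(axis=2)


@dataclass
class BoundaryAnnotation:
    """Manually selected boundary points for one colony image.

    ``outer_points`` trace the outer colony boundary, ``inner_points`` the
    core boundary; both are ``(n, 2)`` arrays of (x, y) pixel coordinates.
    """

    outer_points: np.ndarray
    inner_points: np.ndarray
    image_id: str = ""
    suggested: bool = False

    def __post_init__(self) -> None:
        self.outer_points = np.atleast_2d(np.asarray(self.outer_points, dtype=np.float64))
        self.inner_points = np.atleast_2d(np.asarray(self.inner_points, dtype=np.float64))

    def validate(self, image_shape: tuple[int, int], n_points: int = DEFAULT_N_POINTS) -> None:
        """Check point counts, image bounds and inner/outer consistency."""
        if n_points < 3:
            raise ValidationError(f"annotation point count must be >= 3, got {n_points}")
        counts = {"outer": len(self.outer_points), "inner": len(self.inner_points)}
        for region, cnt in counts.items():
            if cnt != n_points:
                raise ValidationError(
                    f"annotation {self.image_id!r}: expected {n_points} {region} points, got {cnt}"
                )
        h, w = image_shape[:2]
        for region, pts in (("outer", self.outer_points), ("inner", self.inner_points)):
            for i, (x, y) in enumerate(pts):
                if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                    raise ValidationError(
                        f"annotation {self.image_id!r}: {region} point {i} at ({x}, {y}) "
                        f"is outside the {w}x{h} image"
                    )
        cx, cy = image_center(image_shape)
        outer_max = float(np.hypot(self.outer_points[:, 0] - cx, self.outer_points[:, 1] - cy).max())
        inner_d = np.hypot(self.inner_points[:, 0] - cx, self.inner_points[:, 1] - cy)
        if float(inner_d.max()) > outer_max + 1e-9:
            raise ValidationError(
                f"annotation {self.image_id!r}: an inner point lies farther from the image "
                f"center ({inner_d.max():.3f} px) than the farthest outer point ({outer_max:.3f} px)"
            )


def read_annotation(
    path: str | Path,
    image_shape: tuple[int, int],
    n_points: int = DEFAULT_N_POINTS,
) -> BoundaryAnnotation:
    """Parse a boundary-point CSV (columns ``region,x,y``) and validate it."""
    path = Path(path)
    outer: list[tuple[float, float]] = []
    inner: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"region", "x", "y"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected CSV header 'region,x,y', got {reader.fieldnames}")
        for row in reader:
            region = row["region"].strip().lower()
            try:
                pt = (float(row["x"]), float(row["y"]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric coordinate in row {row}") from exc
            if region == "outer":
                outer.append(pt)
            elif region == "inner":
                inner.append(pt)
            else:
                raise FormatError(f"{path}: unknown region {row['region']!r} (expected outer/inner)")
    ann = BoundaryAnnotation(np.array(outer), np.array(inner), image_id=path.stem)
    ann.validate(image_shape, n_points=n_points)
    return ann


def write_annotation(path: str | Path, annotation: BoundaryAnnotation) -> None:
    """Write a boundary annotation in the same ``region,x,y`` CSV dialect."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "x", "y"])
        for x, y in annotation.outer_points:
            writer.writerow(["outer", repr(float(x)), repr(float(y))])
        for x, y in annotation.inner_points:
            writer.writerow(["inner", repr(float(x)), repr(float(y))])


def suggest_boundary_points(
    img: np.ndarray,
    n: int = DEFAULT_N_POINTS,
    threshold: float = 30.0,
) -> tuple[np.ndarray, list[float]]:
    """Suggest outer-boundary points by ray-casting from the image center.

    For ``n`` equally spaced angles, marches a ray outward from the image
    center and records the farthest pixel whose intensity exceeds
    ``threshold``. This is a convenience starting point for manual curation,
    never a substitute for it; callers receive the points together with the
    list of angles (radians) whose ray contained no above-threshold pixel.

    Returns
    -------
    points : (k, 2) float array of suggested (x, y) positions, k <= n
    missing : angles whose ray had no above-threshold pixel
    """
    if n < 3:
        raise ValidationError(f"need at least 3 rays, got {n}")
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale array, got shape {gray.shape}")
    h, w = gray.shape
    cx, cy = image_center(gray.shape)
    points: list[tuple[float, float]] = []
    missing: list[float] = []
    step = 0.5
    for k in range(n):
        theta = 2 * math.pi * k / n
        dx, dy = math.cos(theta), math.sin(theta)
        best: tuple[float, float] | None = None
        t = 0.0
        while True:
            x, y = cx + t * dx, cy + t * dy
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                break
            if gray[yi, xi] > threshold:
                best = (float(xi), float(yi))  # the in-bounds pixel actually tested
            t += step
        if best is None:
            missing.append(theta)
        else:
            points.append(best)
    if missing:
        logger.info("suggest_boundary_points: %d/%d rays had no pixel above %.1f", len(missing), n, threshold)
    return np.array(points, dtype=np.float64).reshape(-1, 2), missing
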