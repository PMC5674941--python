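"""Synthetic colony fluorescence images with recorded ground truth.

The generator emulates the two colony phenotypes the pipeline is meant to
distinguish, as they appear in top-down GFP fluorescence images:

* a *smooth* phenotype (LB-like): a near-uniform bright core whose mean
  intensity holds or rises over the days;
* a *wrinkled* phenotype (LBGM-like): a core crisscrossed by thin
  high-intensity bands over a darker background, where band density rises and
  mean core intensity falls as the biofilm matures.

Each colony is a centered disc whose outer radius grows geometrically between
day 1 and the final expansion ratio while the core radius stays
near-constant; a periphery annulus of intermediate intensity separates core
from background, and additive Gaussian sensor noise is applied last. Wrinkles
are modeled as a zero-mean superposition of 2-4 oriented sinusoidal ridge
sets with per-colony random orientations and phases — enough to produce the
band crossovers the complexity score detects, with no claim to wrinkle
biomechanics.

All randomness flows from a single per-colony seed through a documented
splitting scheme (ridge geometry at stream 17; per-day noise at stream
(29, day)), so datasets regenerate bit-identically. Every generated series is
accompanied by boundary-point CSVs placed exactly on the true radii and a
ground-truth table, which downstream tests use as the recovery oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from biofilmq.errors import ValidationError
from biofilmq.image_io import BoundaryAnnotation, image_center, write_annotation

MANIFEST_NAME = "manifest.json"
GROUND_TRUTH_NAME = "ground_truth.csv"


@dataclass
class SyntheticColonySpec:
    """Generator parameters for one colony series (defaults: smooth preset).

    Radii are in pixels, intensities on the 0-255 scale. ``outer_expansion``
    and ``core_expansion`` are final/initial radius ratios reached on the last
    day via geometric interpolation; ``core_intensity_trend`` is the
    multiplicative per-day factor on the core's mean intensity.
    ``wrinkle_density_day1`` counts bands per 100 px and grows by
    ``wrinkle_density_growth`` per day.
    """

    image_size: tuple[int, int] = (320, 320)  # (H, W)
    days: int = 4
    outer_radius_day1: float = 70.0
    outer_expansion: float = 1.64
    core_radius_day1: float = 58.0
    core_expansion: float = 1.04
    core_base_intensity: float = 120.0
    core_intensity_trend: float = 1.0
    wrinkle_contrast: float = 0.0
    wrinkle_density_day1: float = 3.0
    wrinkle_density_growth: float = 1.0
    noise_sd: float = 4.0
    background_intensity: float = 10.0
    periphery_intensity: float = 140.0
    n_boundary_points: int = 16
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.days < 1:
            raise ValidationError(f"days must be >= 1, got {self.days}")
        if self.outer_radius_day1 <= 0 or self.core_radius_day1 <= 0:
            raise ValidationError("day-1 radii must be positive")
        if self.wrinkle_density_day1 <= 0 or self.wrinkle_density_growth <= 0:
            raise ValidationError("wrinkle densities must be positive")
        for day in range(1, self.days + 1):
            r_out = self.outer_radius(day)
            r_core = self.core_radius(day)
            if r_core > r_out:
                raise ValidationError(
                    f"day {day}: core radius {r_core:.1f} exceeds outer radius {r_out:.1f}"
                )
            if r_out > min(h, w) / 2.0 - 1:
                raise ValidationError(
                    f"day {day}: outer radius {r_out:.1f} does not fit the {w}x{h} image"
                )

    def _radius(self, r1: float, ratio: float, day: int) -> float:
        if self.days == 1:
            return r1
        return r1 * ratio ** ((day - 1) / (self.days - 1))

    def outer_radius(self, day: int) -> float:
        return self._radius(self.outer_radius_day1, self.outer_expansion, day)

    def core_radius(self, day: int) -> float:
        return self._radius(self.core_radius_day1, self.core_expansion, day)

    def core_intensity(self, day: int) -> float:
        return self.core_base_intensity * self.core_intensity_trend ** (day - 1)

    def wrinkle_density(self, day: int) -> float:
        return self.wrinkle_density_day1 * self.wrinkle_density_growth ** (day - 1)


def lb_preset(**overrides) -> SyntheticColonySpec:
    """Smooth phenotype: uniform core, outer radius to 164%, intensity to ~170%."""
    params = dict(
        outer_expansion=1.64,
        core_expansion=1.04,
        core_base_intensity=120.0,
        core_intensity_trend=1.7 ** (1.0 / 3.0),
        wrinkle_contrast=0.0,
    )
    params.update(overrides)
    return SyntheticColonySpec(**params)


def lbgm_preset(**overrides) -> SyntheticColonySpec:
    """Wrinkled phenotype: banded core, outer radius to 205%, core to 126%,
    mean intensity down to ~70%, band density rising day over day."""
    params = dict(
        outer_expansion=2.05,
        core_expansion=1.26,
        core_base_intensity=170.0,
        core_intensity_trend=0.7 ** (1.0 / 3.0),
        wrinkle_contrast=55.0,
        wrinkle_density_day1=3.0,
        wrinkle_density_growth=1.4,
    )
    params.update(overrides)
    return SyntheticColonySpec(**params)


def _ridge_geometry(spec: SyntheticColonySpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-colony band orientations and phases (fixed across days)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 17]))
    k = int(rng.integers(2, 5))
    angles = rng.uniform(0.0, np.pi, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    return angles, phases


def _band_pattern(
    spec: SyntheticColonySpec,
    day: int,
    xs: np.ndarray,
    ys: np.ndarray,
    core_mask: np.ndarray,
) -> np.ndarray:
    """Zero-mean crisscrossing ridge field on the core, amplitude <= ~1."""
    angles, phases = _ridge_geometry(spec)
    freq = spec.wrinkle_density(day) / 100.0  # cycles per pixel
    cx, cy = image_center(spec.image_size)
    pattern = np.zeros_like(xs, dtype=np.float64)
    for phi, psi in zip(angles, phases):
        u = (xs - cx) * np.cos(phi) + (ys - cy) * np.sin(phi)
        pattern += np.cos(2.0 * np.pi * freq * u + psi)
    pattern /= len(angles)
    pattern -= pattern[core_mask].mean()  # exact zero mean over the core disc
    return pattern


def generate_day_image(spec: SyntheticColonySpec, day: int) -> tuple[np.ndarray, dict]:
    """Render one day's image and its ground-truth row.

    Returns the 8-bit RGB image (GFP signal identical in all three channels,
    so grayscale conversion is the identity on intent) and a dict with the
    applied outer/core radii, pre-noise core mean intensity and wrinkle
    parameters.
    """
    spec.validate()
    if not (1 <= day <= spec.days):
        raise ValidationError(f"day must be in [1, {spec.days}], got {day}")
    h, w = spec.image_size
    cx, cy = image_center(spec.image_size)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    dist = np.hypot(xs - cx, ys - cy)

    r_out = spec.outer_radius(day)
    r_core = spec.core_radius(day)
    core_mask = dist <= r_core
    periphery_mask = (dist > r_core) & (dist <= r_out)

    field = np.full((h, w), spec.background_intensity, dtype=np.float64)
    field[periphery_mask] = spec.periphery_intensity
    core_value = spec.core_intensity(day)
    field[core_mask] = core_value
    if spec.wrinkle_contrast > 0:
        pattern = _band_pattern(spec, day, xs, ys, core_mask)
        field[core_mask] += spec.wrinkle_contrast * pattern[core_mask]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 29, day]))
        field += rng.normal(0.0, spec.noise_sd, size=field.shape)

    quantized = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    rgb = np.repeat(quantized[:, :, None], 3, axis=2)
    truth = {
        "day": day,
        "outer_radius": r_out,
        "core_radius": r_core,
        "core_mean_intensity": core_value,
        "wrinkle_contrast": spec.wrinkle_contrast,
        "wrinkle_density": spec.wrinkle_density(day) if spec.wrinkle_contrast > 0 else 0.0,
        "noise_sd": spec.noise_sd,
    }
    return rgb, truth


def _true_annotation(spec: SyntheticColonySpec, day: int, image_id: str) -> BoundaryAnnotation:
    """Boundary points placed exactly on the true radii at uniform angles."""
    cx, cy = image_center(spec.image_size)
    n = spec.n_boundary_points
    angles = 2.0 * np.pi * np.arange(n) / n
    def ring(r: float) -> np.ndarray:
        return np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
    return BoundaryAnnotation(
        outer_points=ring(spec.outer_radius(day)),
        inner_points=ring(spec.core_radius(day)),
        image_id=image_id,
    )


def generate_series(
    spec: SyntheticColonySpec,
    out_dir: str | Path | None = None,
    colony_id: str = "colony",
) -> tuple[list[tuple[np.ndarray, dict]], list[BoundaryAnnotation]]:
    """Generate all days of one colony, optionally writing them to disk.

    When ``out_dir`` is given, writes ``day<k>.png``, ``day<k>.points.csv``
    and ``ground_truth.csv`` into it.
    """
    spec.validate()
    results = []
    annotations = []
    for day in range(1, spec.days + 1):
        img, truth = generate_day_image(spec, day)
        ann = _true_annotation(spec, day, image_id=f"{colony_id}_day{day}")
        results.append((img, truth))
        annotations.append(ann)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for day, ((img, _), ann) in enumerate(zip(results, annotations), start=1):
            Image.fromarray(img, mode="RGB").save(out / f"day{day}.png")
            write_annotation(out / f"day{day}.points.csv", ann)
        pd.DataFrame([t for _, t in results]).to_csv(out / GROUND_TRUTH_NAME, index=False)
    return results, annotations


def _colony_seed(master_seed: int, cohort_index: int, colony_index: int) -> int:
    seq = np.random.SeedSequence([master_seed, cohort_index, colony_index])
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohorts(
    out_dir: str | Path,
    n_lb: int = 11,
    n_lbgm: int = 8,
    presets: dict[str, SyntheticColonySpec] | None = None,
    seed: int = 0,
) -> Path:
    """Write a reproducible two-cohort dataset and return the manifest path.

    Layout: ``<out>/<cohort>/<colony_id>/day<k>.png`` with matching
    ``day<k>.points.csv`` and ``ground_truth.csv``, plus a ``manifest.json``
    recording specs, seeds and files. The same master seed always regenerates
    the identical dataset.
    """
    if n_lb < 1 or n_lbgm < 1:
        raise ValidationError(f"cohort sizes must be >= 1, got n_lb={n_lb}, n_lbgm={n_lbgm}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if presets is None:
        presets = {"LB": lb_preset(), "LBGM": lbgm_preset()}
    counts = {"LB": n_lb, "LBGM": n_lbgm}
    manifest: dict = {"seed": seed, "cohorts": {}}
    for c_idx, (cohort, template) in enumerate(sorted(presets.items())):
        n = counts.get(cohort, n_lb)
        entries = []
        for i in range(n):
            colony_id = f"{cohort.lower()}_{i + 1:02d}"
            colony_seed = _colony_seed(seed, c_idx, i)
            spec = dataclasses.replace(template, rng_seed=colony_seed)
            colony_dir = out / cohort / colony_id
            generate_series(spec, out_dir=colony_dir, colony_id=colony_id)
            entries.append(
                {
                    "colony_id": colony_id,
                    "seed": colony_seed,
                    "days": spec.days,
                    "path": str(Path(cohort) / colony_id),
                    "spec": dataclasses.asdict(spec),
                }
            )
        manifest["cohorts"][cohort] = entries
    manifest_path = out / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
        fh.write("\n")
    return manifest_path
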