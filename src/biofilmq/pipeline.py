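"""End-to-end analysis: images + annotations -> tidy CSV reports.

The expected dataset layout (the one the synthetic generator writes) is

    <images>/<cohort>/<colony_id>/day<k>.png
    <annotations>/<cohort>/<colony_id>/day<k>.points.csv

with the annotation tree defaulting to the image tree. Day indices are the
timepoints. ``analyze_dataset`` measures every image (radii, bounding
circles, core intensity, spiral complexity), assembles per-colony time
series, and writes the report files listed in ``REPORT_FILES`` plus a JSON
run summary with provenance (config, config hash, input hashes, package
version) sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

import biofilmq
from biofilmq import complexity as cx
from biofilmq import geometry, image_io, kinetics, stats
from biofilmq.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "region_measurements.csv",
    "kinetics.csv",
    "cohort_summary.csv",
    "complexity.csv",
    "max_complexity.csv",
    "anova.csv",
    "stats.csv",
    "run_summary.json",
)

_DAY_RE = re.compile(r"^day(\d+)\.png$")


@dataclass
class RunConfig:
    """Analysis parameters; the defaults are the method's canonical values
    (2000 spiral samples, 20-px windows, 16 boundary points)."""

    n_samples: int = cx.DEFAULT_N_SAMPLES
    pitch: float = cx.DEFAULT_PITCH
    window: int = cx.DEFAULT_WINDOW
    n_boundary_points: int = image_io.DEFAULT_N_POINTS
    spiral_center: str = "image"  # "image" | "core" (core bounding-circle center)
    intensity_circle: str = "minimal"  # "minimal" | "image" (image-centered, avg-radius)
    interpolation: str = "bilinear"
    equal_var: bool = False
    paired: bool = False
    bonferroni_m: int | None = None
    export_signals: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.spiral_center not in ("image", "core"):
            raise ValidationError(f"spiral_center must be 'image' or 'core', got {self.spiral_center!r}")
        if self.intensity_circle not in ("minimal", "image"):
            raise ValidationError(
                f"intensity_circle must be 'minimal' or 'image', got {self.intensity_circle!r}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Read a flat TOML config file whose keys mirror the CLI flags."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown config keys in {path}: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def discover_colonies(images_dir: str | Path) -> list[dict]:
    """Find ``<cohort>/<colony>/day<k>.png`` series under the image root."""
    root = Path(images_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory not found: {root}")
    colonies = []
    for cohort_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for colony_dir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
            days = {}
            for f in colony_dir.iterdir():
                m = _DAY_RE.match(f.name)
                if m:
                    days[int(m.group(1))] = f
            if days:
                colonies.append(
                    {
                        "cohort": cohort_dir.name,
                        "colony_id": colony_dir.name,
                        "days": dict(sorted(days.items())),
                        "rel_dir": Path(cohort_dir.name) / colony_dir.name,
                    }
                )
    if not colonies:
        raise ValidationError(f"no '<cohort>/<colony>/day<k>.png' series found under {root}")
    return colonies


def _measure_colony(
    entry: dict,
    annotations_dir: Path,
    config: RunConfig,
    signals_dir: Path | None,
) -> tuple[kinetics.ColonyTimeSeries, list[dict], list[dict]]:
    whole_ms, core_ms, cpx_rows, region_rows = [], [], [], []
    timepoints = sorted(entry["days"])
    for day in timepoints:
        img_path = entry["days"][day]
        image_id = f"{entry['colony_id']}_day{day}"
        rgb = image_io.load_image(img_path)
        gray = image_io.to_grayscale(rgb)
        ann_path = annotations_dir / entry["rel_dir"] / f"day{day}.points.csv"
        if not ann_path.exists():
            raise ValidationError(f"missing annotation file for {img_path}: {ann_path}")
        ann = image_io.read_annotation(ann_path, gray.shape, n_points=config.n_boundary_points)
        center = image_io.image_center(gray.shape)

        whole = geometry.measure_region(gray, ann.outer_points, center)
        core_circle = geometry.minimal_bounding_circle(ann.inner_points)
        core_avg_radius = geometry.average_radius(ann.inner_points, center)
        if config.intensity_circle == "image":
            intensity_circle = geometry.Circle(center[0], center[1], core_avg_radius)
        else:
            intensity_circle = core_circle
        core_mean, core_count = geometry.mean_intensity_in_circle(gray, intensity_circle)
        core = geometry.RegionMeasurement(
            avg_radius=core_avg_radius,
            bounding_circle=core_circle,
            mean_intensity=core_mean,
            pixel_count=core_count,
        )
        whole_ms.append(whole)
        core_ms.append(core)

        spiral_center = center if config.spiral_center == "image" else (core_circle.cx, core_circle.cy)
        path = cx.spiral_path(spiral_center, n_samples=config.n_samples, pitch=config.pitch)
        signal = cx.sample_signal(gray, path, interpolation=config.interpolation)
        if float(path.radii.max()) > core_circle.r:
            logger.warning(
                "%s: spiral max radius %.1f px exceeds core circle radius %.1f px",
                image_id,
                float(path.radii.max()),
                core_circle.r,
            )
        score = cx.ComplexityScore(
            amplitude=cx.windowed_amplitude(signal, config.window),
            frequency=cx.windowed_frequency(signal, config.window),
            window=config.window,
        )
        if signals_dir is not None:
            sig_path = signals_dir / f"{image_id}.signal.csv"
            pd.DataFrame(
                {"arc_length_px": np.arange(len(signal), dtype=float), "intensity": signal}
            ).to_csv(sig_path, index=False)

        for region, m in (("whole", whole), ("core", core)):
            region_rows.append(
                {
                    "image_id": image_id,
                    "colony_id": entry["colony_id"],
                    "cohort": entry["cohort"],
                    "timepoint": day,
                    "region": region,
                    "avg_radius_px": m.avg_radius,
                    "circle_cx": m.bounding_circle.cx,
                    "circle_cy": m.bounding_circle.cy,
                    "circle_r_px": m.bounding_circle.r,
                    "mean_intensity": m.mean_intensity,
                    "pixel_count": m.pixel_count,
                }
            )
        cpx_rows.append(
            {
                "image_id": image_id,
                "colony_id": entry["colony_id"],
                "cohort": entry["cohort"],
                "timepoint": day,
                "amplitude": score.amplitude,
                "frequency": score.frequency,
                "n_samples": config.n_samples,
                "pitch": config.pitch,
                "window": config.window,
            }
        )
    series = kinetics.ColonyTimeSeries(
        colony_id=entry["colony_id"],
        cohort=entry["cohort"],
        timepoints=np.array(timepoints, dtype=float),
        whole=whole_ms,
        core=core_ms,
    )
    return series, region_rows, cpx_rows


def _stats_reports(
    kin_table: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cohort x metric: ANOVA across days + day-vs-baseline post hoc tests."""
    anova_rows, stat_rows = [], []
    for (cohort, metric), grp in kin_table.groupby(["cohort", "metric"], sort=True):
        days = sorted(grp["timepoint"].unique())
        groups = [grp.loc[grp["timepoint"] == d, "value"].to_numpy() for d in days]
        family = f"{cohort}:{metric}"
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            logger.info("skipping stats for %s: too few days or colonies", family)
            continue
        labels = [f"day{int(d)}" for d in days]
        (f_stat, p_anova), pairwise = stats.day_family_tests(
            groups,
            labels,
            m=config.bonferroni_m,
            equal_var=config.equal_var,
            paired=config.paired,
        )
        n_total = sum(len(g) for g in groups)
        anova_rows.append(
            {
                "family": family,
                "F": f_stat,
                "df_between": len(groups) - 1,
                "df_within": n_total - len(groups),
                "p": p_anova,
            }
        )
        for r in pairwise:
            stat_rows.append(
                {
                    "family": family,
                    "comparison": r.pair,
                    "t": r.t,
                    "p_raw": r.p_raw,
                    "m": r.m,
                    "p_adjusted": r.p_adjusted,
                    "tier": r.tier,
                }
            )
    anova_cols = ["family", "F", "df_between", "df_within", "p"]
    stat_cols = ["family", "comparison", "t", "p_raw", "m", "p_adjusted", "tier"]
    return (
        pd.DataFrame(anova_rows, columns=anova_cols),
        pd.DataFrame(stat_rows, columns=stat_cols),
    )


def _hash_inputs(colonies: list[dict], annotations_dir: Path) -> dict[str, str]:
    hashes = {}
    for entry in colonies:
        for day, img_path in entry["days"].items():
            for p in (img_path, annotations_dir / entry["rel_dir"] / f"day{day}.points.csv"):
                if p.exists():
                    hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return hashes


def analyze_dataset(
    images_dir: str | Path,
    out_dir: str | Path,
    annotations_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> Path:
    """Run the full measurement pipeline and write the report files.

    Returns the output directory. The run is deterministic for fixed inputs:
    rerunning produces byte-identical CSV payloads (the JSON summary carries
    the only timestamp).
    """
    config = config or RunConfig()
    config.validate()
    images_dir = Path(images_dir)
    annotations_dir = Path(annotations_dir) if annotations_dir is not None else images_dir
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signals_dir = None
    if config.export_signals:
        signals_dir = out / "signals"
        signals_dir.mkdir(exist_ok=True)

    colonies = discover_colonies(images_dir)
    series_list, region_rows, cpx_rows, errors = [], [], [], []
    for entry in colonies:
        try:
            series, regions, cpx = _measure_colony(entry, annotations_dir, config, signals_dir)
        except (ValidationError, FormatError, FileNotFoundError) as exc:
            errors.append(f"{entry['cohort']}/{entry['colony_id']}: {exc}")
            continue
        series_list.append(series)
        region_rows.extend(regions)
        cpx_rows.extend(cpx)
    if errors:
        raise ValidationError("analysis failed for some colonies:\n" + "\n".join(errors))

    pd.DataFrame(region_rows).to_csv(out / "region_measurements.csv", index=False)
    kin_table = kinetics.kinetics_table(series_list)
    kin_table.to_csv(out / "kinetics.csv", index=False)
    kinetics.cohort_summary(series_list).to_csv(out / "cohort_summary.csv", index=False)
    cpx_table = pd.DataFrame(cpx_rows)
    cpx_table.to_csv(out / "complexity.csv", index=False)

    max_rows = []
    for (cohort, colony_id), grp in cpx_table.groupby(["cohort", "colony_id"], sort=True):
        scores = [
            cx.ComplexityScore(a, f, config.window)
            for a, f in zip(grp["amplitude"], grp["frequency"])
        ]
        amp, freq = cx.max_complexity(scores)
        max_rows.append(
            {"colony_id": colony_id, "cohort": cohort, "max_amplitude": amp, "max_frequency": freq}
        )
    pd.DataFrame(max_rows).to_csv(out / "max_complexity.csv", index=False)

    anova_table, stats_table = _stats_reports(kin_table, config)
    anova_table.to_csv(out / "anova.csv", index=False)
    stats_table.to_csv(out / "stats.csv", index=False)

    summary = {
        "package": "biofilmq",
        "version": biofilmq.__version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "images_dir": str(images_dir),
        "annotations_dir": str(annotations_dir),
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "n_colonies": len(series_list),
        "n_images": int(len(region_rows) / 2),
        "input_hashes": _hash_inputs(colonies, annotations_dir),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote reports for %d colonies to %s", len(series_list), out)
    return out
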