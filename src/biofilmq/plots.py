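"""Figure generation from the pipeline's CSV reports (file output only)."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from biofilmq.errors import FormatError

logger = logging.getLogger(__name__)

_METRIC_LABELS = {
    "colony_radius_pct": "Colony radius (% of day 1)",
    "core_radius_pct": "Core radius (% of day 1)",
    "core_intensity_pct": "Core GFP intensity (% of day 1)",
}


def _read_report(path: Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse report {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def plot_trajectories(summary_csv: str | Path, out_dir: str | Path) -> list[Path]:
    """One mean +/- SD trajectory figure per metric, cohorts overlaid."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _read_report(Path(summary_csv), {"cohort", "timepoint", "metric", "mean", "sd"})
    written = []
    for metric, grp in df.groupby("metric"):
        if grp["mean"].isna().all():
            logger.warning("metric %s has no values; skipping plot", metric)
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for cohort, cg in grp.groupby("cohort"):
            cg = cg.sort_values("timepoint")
            ax.errorbar(cg["timepoint"], cg["mean"], yerr=cg["sd"], marker="o", capsize=3, label=cohort)
        ax.set_xlabel("Day")
        ax.set_ylabel(_METRIC_LABELS.get(metric, metric))
        ax.legend()
        fig.tight_layout()
        path = out / f"trajectory_{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written


def plot_complexity_scatter(max_complexity_csv: str | Path, out_dir: str | Path) -> Path:
    """Maximal amplitude vs frequency scatter, one color per cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _read_report(Path(max_complexity_csv), {"cohort", "max_amplitude", "max_frequency"})
    fig, ax = plt.subplots(figsize=(5, 4))
    for cohort, cg in df.groupby("cohort"):
        ax.scatter(cg["max_amplitude"], cg["max_frequency"], label=cohort, alpha=0.8)
    ax.set_xlabel("Maximal amplitude (intensity units)")
    ax.set_ylabel("Maximal frequency (intensity variance)")
    ax.legend()
    fig.tight_layout()
    path = out / "amplitude_frequency_scatter.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_signals(signals_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Spiral-signal line plots from exported per-image signal CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for sig_csv in sorted(Path(signals_dir).glob("*.signal.csv")):
        df = _read_report(sig_csv, {"arc_length_px", "intensity"})
        if df["intensity"].isna().all():
            logger.warning("%s has no intensity values; skipping", sig_csv)
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(df["arc_length_px"], df["intensity"], lw=0.8)
        ax.set_xlabel("Arc length along spiral (px)")
        ax.set_ylabel("Intensity (0-255)")
        ax.set_title(sig_csv.stem.replace(".signal", ""))
        fig.tight_layout()
        path = out / f"{sig_csv.stem.replace('.signal', '')}_signal.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written


def plot_reports(reports_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Render all standard figures available in a report directory."""
    reports = Path(reports_dir)
    written: list[Path] = []
    summary = reports / "cohort_summary.csv"
    if summary.exists():
        written.extend(plot_trajectories(summary, out_dir))
    max_cpx = reports / "max_complexity.csv"
    if max_cpx.exists():
        written.append(plot_complexity_scatter(max_cpx, out_dir))
    signals = reports / "signals"
    if signals.is_dir():
        written.extend(plot_signals(signals, out_dir))
    if not written:
        logger.warning("no recognized report files under %s", reports)
    return written
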