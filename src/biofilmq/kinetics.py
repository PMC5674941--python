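"""Growth and intensity trajectories relative to the day-1 baseline.

Each colony yields three trajectories over its (strictly increasing)
timepoints, all expressed as a percentage of the first timepoint:

* ``colony_radius_pct`` — average outer-boundary radius,
* ``core_radius_pct``   — average core-boundary radius,
* ``core_intensity_pct`` — mean GFP intensity inside the core bounding circle.

Cohort summaries report per-timepoint mean and sample standard deviation
(n-1 denominator) across colonies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from biofilmq.errors import ValidationError
from biofilmq.geometry import RegionMeasurement

logger = logging.getLogger(__name__)

METRICS = ("colony_radius_pct", "core_radius_pct", "core_intensity_pct")


@dataclass
class ColonyTimeSeries:
    """Ordered per-day region measurements for one colony."""

    colony_id: str
    cohort: str
    timepoints: np.ndarray
    whole: list[RegionMeasurement]
    core: list[RegionMeasurement]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=np.float64)
        if self.timepoints.size == 0:
            raise ValidationError(f"colony {self.colony_id!r}: empty timepoint list")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError(f"colony {self.colony_id!r}: timepoints must be strictly increasing")
        for region, ms in (("whole", self.whole), ("core", self.core)):
            if len(ms) != len(self.timepoints):
                raise ValidationError(
                    f"colony {self.colony_id!r}: {len(ms)} {region} measurements for "
                    f"{len(self.timepoints)} timepoints"
                )
            for t, m in zip(self.timepoints, ms):
                if m is None:
                    raise ValidationError(
                        f"colony {self.colony_id!r}: missing {region} measurement at timepoint {t}"
                    )


def relative_series(values: np.ndarray) -> np.ndarray:
    """Express a series as a percentage of its first value (baseline = 100)."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise ValidationError("relative_series needs at least one value")
    if vals[0] <= 0:
        raise ValidationError(f"baseline value must be positive, got {vals[0]}")
    return 100.0 * vals / vals[0]


def colony_kinetics(series: ColonyTimeSeries) -> dict[str, np.ndarray]:
    """Relative radius and intensity trajectories for one colony."""
    return {
        "colony_radius_pct": relative_series([m.avg_radius for m in series.whole]),
        "core_radius_pct": relative_series([m.avg_radius for m in series.core]),
        "core_intensity_pct": relative_series([m.mean_intensity for m in series.core]),
    }


def kinetics_table(series_list: list[ColonyTimeSeries]) -> pd.DataFrame:
    """Tidy per-colony trajectory table: colony_id, cohort, timepoint, metric, value."""
    rows = []
    for s in series_list:
        traj = colony_kinetics(s)
        for metric in METRICS:
            for t, v in zip(s.timepoints, traj[metric]):
                rows.append((s.colony_id, s.cohort, float(t), metric, float(v)))
    return pd.DataFrame(rows, columns=["colony_id", "cohort", "timepoint", "metric", "value"])


def cohort_summary(series_list: list[ColonyTimeSeries]) -> pd.DataFrame:
    """Per-timepoint mean and SD of each trajectory across colonies of a cohort.

    All series must share the same timepoint grid. SD uses the sample (n-1)
    denominator; a single-colony cohort gets SD 0 by convention (logged).
    """
    if not series_list:
        raise ValidationError("cohort_summary needs at least one colony series")
    grid = series_list[0].timepoints
    for s in series_list[1:]:
        if len(s.timepoints) != len(grid) or not np.allclose(s.timepoints, grid):
            raise ValidationError(
                f"colony {s.colony_id!r} timepoints {s.timepoints.tolist()} do not match "
                f"the cohort grid {grid.tolist()}"
            )
    table = kinetics_table(series_list)
    rows = []
    for (cohort, metric, t), grp in table.groupby(["cohort", "metric", "timepoint"], sort=True):
        vals = grp["value"].to_numpy()
        n = len(vals)
        if n == 1:
            logger.info("cohort %s, metric %s: single colony, reporting SD 0", cohort, metric)
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append((cohort, float(t), metric, float(np.mean(vals)), sd, n))
    return pd.DataFrame(rows, columns=["cohort", "timepoint", "metric", "mean", "sd", "n"])
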