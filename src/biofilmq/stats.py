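"""Statistical layer: one-way ANOVA across days followed by post hoc t-tests
against the day-1 baseline with Bonferroni correction.

Defaults follow common practice where the method is underspecified: t-tests
are two-sided Welch tests (unpaired), and the Bonferroni multiplier m is the
number of post hoc comparisons actually made in the family. Significance
tiers are rendered on adjusted p-values: ``*`` for p < 0.05 and ``#`` for
p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from biofilmq.errors import ValidationError


@dataclass(frozen=True)
class PairwiseResult:
    """One baseline-vs-group comparison of the post hoc family."""

    pair: str
    t: float
    p_raw: float
    m: int
    p_adjusted: float
    tier: str


def significance_tier(p: float) -> str:
    """Render the significance marker used in the reports (* <0.05, # <0.01)."""
    if p < 0.01:
        return "#"
    if p < 0.05:
        return "*"
    return ""


def _as_groups(groups: list[np.ndarray], min_groups: int) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrs) < min_groups:
        raise ValidationError(f"need at least {min_groups} groups, got {len(arrs)}")
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise ValidationError(f"group {i} has n={len(g)} < 2 observations")
    return arrs


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Degenerate inputs are resolved explicitly: zero within-group variance with
    unequal means gives ``(inf, 0.0)``; a completely constant data set gives
    ``(0.0, 1.0)``.
    """
    arrs = _as_groups(groups, min_groups=2)
    means = [g.mean() for g in arrs]
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return (0.0, 1.0)
        return (math.inf, 0.0)
    f, p = sps.f_oneway(*arrs)
    return (float(f), float(p))


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, m * p_raw)``."""
    if m < 1:
        raise ValidationError(f"number of comparisons m must be >= 1, got {m}")
    return min(1.0, m * p_raw)


def posthoc_bonferroni(
    baseline: np.ndarray,
    others: list[np.ndarray],
    m: int | None = None,
    labels: list[str] | None = None,
    equal_var: bool = False,
    paired: bool = False,
) -> list[PairwiseResult]:
    """Two-sided t-tests of each group against the baseline, Bonferroni-corrected.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled Student test, ``paired=True`` for paired samples of equal length).
    ``m`` defaults to the number of comparisons performed and must not be
    smaller than it.
    """
    base = np.asarray(baseline, dtype=np.float64).ravel()
    arrs = _as_groups(others, min_groups=1)
    if len(base) < 2:
        raise ValidationError(f"baseline has n={len(base)} < 2 observations")
    n_cmp = len(arrs)
    if m is None:
        m = n_cmp
    if m < n_cmp:
        raise ValidationError(f"m={m} is smaller than the {n_cmp} comparisons performed")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(n_cmp)]
    results = []
    for label, g in zip(labels, arrs):
        if paired:
            if len(g) != len(base):
                raise ValidationError(f"paired test {label!r}: lengths {len(base)} vs {len(g)} differ")
            t, p = sps.ttest_rel(base, g)
        else:
            t, p = sps.ttest_ind(base, g, equal_var=equal_var)
        t, p = float(t), float(p)
        if math.isnan(t):  # both samples constant and equal: no evidence of difference
            t, p = 0.0, 1.0
        p_adj = bonferroni_adjust(p, m)
        results.append(
            PairwiseResult(pair=label, t=t, p_raw=p, m=m, p_adjusted=p_adj, tier=significance_tier(p_adj))
        )
    return results


def day_family_tests(
    groups: list[np.ndarray],
    labels: list[str],
    m: int | None = None,
    equal_var: bool = False,
    paired: bool = False,
) -> tuple[tuple[float, float], list[PairwiseResult]]:
    """ANOVA over all day groups plus the day-vs-baseline post hoc family."""
    if len(groups) != len(labels):
        raise ValidationError("groups and labels must have the same length")
    anova = anova_oneway(groups)
    pairwise = posthoc_bonferroni(
        groups[0],
        groups[1:],
        m=m,
        labels=[f"{labels[0]} vs {lab}" for lab in labels[1:]],
        equal_var=equal_var,
        paired=paired,
    )
    return anova, pairwise
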