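"""Per-sample exon usage and the Mann-Whitney group comparison.

Usage of a (novel) exon in one sample is the inclusion fraction
``inclusion / total`` over the event locus — any per-sample
numerator/denominator pair fits, so junction-read and
transcript-quantification definitions both work.  ``0/0`` is missing, not
zero: a sample with no evidence at the locus is excluded from the test.

The two-group comparison is a two-sided Mann-Whitney U test: exact (full
permutation distribution, doubled smaller tail) when the pooled sample size
is small and the data are tie-free, otherwise the normal approximation with
tie-corrected variance and continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from varipept.quant import GroupDesign
from varipept.diffexpr import DIRECTION_DOWN, DIRECTION_NONE, DIRECTION_UP


@dataclass(frozen=True)
class UsageResult:
    """Outcome of a novel-exon usage comparison."""

    per_sample_usage: Mapping[str, float]
    u_statistic: float
    p_value: float
    median_case: float
    median_control: float
    direction: str


def usage_fraction(inclusion: int, total: int) -> float:
    """Inclusion fraction; ``nan`` (missing) when there is no evidence."""
    if inclusion < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if inclusion > total:
        raise ValueError(f"inclusion {inclusion} exceeds total {total}")
    if total == 0:
        return math.nan
    return inclusion / total


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic for ``group_a``.  Missing
    values (NaN) are removed first.  The exact null distribution is used
    when ``len(a) + len(b) <= exact_threshold`` and the pooled values are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("a group is empty after removing missing values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def test_novel_exon_usage(
    usage_counts: pd.DataFrame,
    design: GroupDesign,
    exact_threshold: int = 25,
) -> UsageResult:
    """Compare novel-exon usage between cases and controls.

    ``usage_counts`` needs columns ``sample``, ``inclusion``, ``total``.
    Samples with ``total == 0`` are excluded as missing; at least 2 usable
    samples per group are required.
    """
    required = {"sample", "inclusion", "total"}
    if not required <= set(usage_counts.columns):
        raise ValueError(f"usage table must have columns {sorted(required)}")
    usage = {
        str(row["sample"]): usage_fraction(int(row["inclusion"]), int(row["total"]))
        for _, row in usage_counts.iterrows()
    }
    case_vals = np.array(
        [usage[s] for s in design.cases if s in usage and not math.isnan(usage[s])]
    )
    control_vals = np.array(
        [usage[s] for s in design.controls if s in usage and not math.isnan(usage[s])]
    )
    if case_vals.size < 2 or control_vals.size < 2:
        raise ValueError("need usage for >= 2 samples in each group")
    u, p = mann_whitney_u(case_vals, control_vals, exact_threshold=exact_threshold)
    med_case = float(np.median(case_vals))
    med_control = float(np.median(control_vals))
    if med_case > med_control:
        direction = DIRECTION_UP
    elif med_case < med_control:
        direction = DIRECTION_DOWN
    else:
        direction = DIRECTION_NONE
    return UsageResult(
        per_sample_usage=usage,
        u_statistic=u,
        p_value=p,
        median_case=med_case,
        median_control=med_control,
        direction=direction,
    )
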