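"""Study-level summary statistics: group means ± SEM, Student's t-test,
regression summaries and Tukey boxplot five-number summaries.

The comparison convention is the classic pooled-variance two-tailed unpaired
Student's t-test (a Welch variant is available by flag); p ≤ 0.05 is the
reported significance threshold but nothing is enforced.  Boxplot summaries
use median, quartiles and whiskers at the most extreme points within 1.5×
the interquartile range.  Raw p-values are reported without multiple-testing
correction and labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float | None


@dataclass
class BoxplotSummary:
    """Five-number summary with Tukey 1.5×IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: list[float]


@dataclass
class SummaryStats:
    groups: list[GroupSummary]
    t_statistic: float | None
    p_value: float | None
    test: str | None
    note: str | None = None
    significance_threshold: float = 0.05

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= self.significance_threshold


def boxplot_summary(values) -> BoxplotSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
    )


def summarize(
    group_a, group_b=None, welch: bool = False
) -> SummaryStats:
    """Mean ± SEM per group plus a two-tailed unpaired t-test when two groups
    of n ≥ 2 are given; with smaller groups the test is omitted with a note."""
    groups = [np.asarray(g, dtype=float) for g in (group_a, group_b) if g is not None]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    summaries = [
        GroupSummary(
            n=int(g.size),
            mean=float(g.mean()),
            sem=float(sps.sem(g)) if g.size >= 2 else None,
        )
        for g in groups
    ]
    if len(groups) == 2 and all(g.size >= 2 for g in groups):
        t, p = sps.ttest_ind(groups[0], groups[1], equal_var=not welch)
        if np.isnan(t):  # zero pooled variance with identical means
            t, p = 0.0, 1.0
        return SummaryStats(
            groups=summaries,
            t_statistic=float(t),
            p_value=float(p),
            test="welch" if welch else "student",
        )
    note = None
    if len(groups) == 2:
        note = "t-test omitted: a group has fewer than 2 observations"
    return SummaryStats(
        groups=summaries, t_statistic=None, p_value=None, test=None, note=note
    )
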