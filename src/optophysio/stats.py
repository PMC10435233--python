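"""Per-larva aggregation and the study's hypothesis-testing procedures.

Group summaries are mean +- SEM over per-larva values. Two test procedures
are provided: the two-sided Wilcoxon rank-sum test (exact distribution for
small tie-free samples, tie-corrected normal approximation otherwise) and
one-way ANOVA followed by Tukey's HSD post hoc comparisons. Paired trial-1
vs trial-6 effects use the Wilcoxon signed-rank test on per-larva
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_group",
    "per_larva_average",
    "rank_sum_test",
    "anova_tukey",
    "trial_effect_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- SEM summary of per-larva values for one group."""

    label: str
    n: int
    mean: float
    sem: float
    values: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    comparison: str = ""
    adjustment: str = "none"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def summarize_group(label: str, values: Sequence[float]) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("empty group")
    sem = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
    return GroupSummary(label, len(v), float(v.mean()), sem, tuple(v))


def per_larva_average(trials: pd.DataFrame, value_cols: Sequence[str],
                      larva_col: str = "larva_id",
                      exclude_col: Optional[str] = None) -> pd.DataFrame:
    """One row per larva: the mean of each metric over its valid trials.

    Rows flagged in ``exclude_col`` are dropped first; larvae left with no
    valid trials are dropped with a warning.
    """
    df = trials.copy()
    if exclude_col is not None and exclude_col in df.columns:
        df = df[~df[exclude_col].astype(bool)]
    dropped = set(trials[larva_col].unique()) - set(df[larva_col].unique())
    for larva in sorted(dropped):
        warnings.warn(f"larva {larva} has no valid trials; dropped")
    if df.empty:
        raise ValueError("no valid trials for any larva")
    return (df.groupby(larva_col)[list(value_cols)]
              .mean()
              .reset_index())


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float],
                  comparison: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The exact null distribution is used when the combined sample size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction. If every pooled value is identical, the test is fully
    degenerate and p = 1 by symmetry.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult("wilcoxon_rank_sum", len(a) * len(b) / 2.0, 1.0,
                          comparison)
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= 20) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(min(res.pvalue, 1.0)), comparison)


def anova_tukey(groups: dict[str, Sequence[float]]) -> list[TestResult]:
    """One-way ANOVA omnibus test followed by Tukey HSD pairwise comparisons.

    Returns the omnibus result first, then one result per group pair with
    studentized-range-adjusted p-values. Zero total variance (all values in
    all groups identical) leaves F undefined and is rejected.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("zero variance in all groups; F statistic undefined")
    f_res = sps.f_oneway(*arrays)
    out = [TestResult("one_way_anova", float(f_res.statistic),
                      float(f_res.pvalue), "omnibus")]
    hsd = sps.tukey_hsd(*arrays)
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(TestResult(
                "tukey_hsd", float(hsd.statistic[i, j]),
                float(min(max(hsd.pvalue[i, j], 0.0), 1.0)),
                f"{labels[i]} vs {labels[j]}", adjustment="tukey"))
    return out


def trial_effect_table(trials: pd.DataFrame, value_col: str,
                       larva_col: str = "larva_id",
                       trial_col: str = "trial_index",
                       trial_a: int = 1, trial_b: int = 6,
                       ) -> tuple[pd.DataFrame, TestResult]:
    """Paired comparison of trial ``trial_a`` vs ``trial_b`` per larva.

    Returns a table of per-larva values and differences (b - a) and a
    Wilcoxon signed-rank test on the paired differences (p = 1 when every
    difference is zero).
    """
    wide = (trials[trials[trial_col].isin([trial_a, trial_b])]
            .pivot_table(index=larva_col, columns=trial_col,
                         values=value_col, aggfunc="mean"))
    wide = wide.dropna(subset=[c for c in (trial_a, trial_b) if c in wide.columns]
                       if {trial_a, trial_b} <= set(wide.columns) else wide.columns)
    if not {trial_a, trial_b} <= set(wide.columns) or wide.empty:
        raise ValueError("no larvae with both trials present")
    table = pd.DataFrame({
        larva_col: wide.index,
        f"trial_{trial_a}": wide[trial_a].to_numpy(),
        f"trial_{trial_b}": wide[trial_b].to_numpy(),
    })
    table["difference"] = table[f"trial_{trial_b}"] - table[f"trial_{trial_a}"]
    diffs = table["difference"].to_numpy()
    if np.all(diffs == 0):
        test = TestResult("wilcoxon_signed_rank", 0.0, 1.0,
                          f"trial {trial_b} vs trial {trial_a}")
    else:
        res = sps.wilcoxon(diffs)
        test = TestResult("wilcoxon_signed_rank", float(res.statistic),
                          float(res.pvalue), f"trial {trial_b} vs trial {trial_a}")
    return table, test
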