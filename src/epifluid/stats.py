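"""Group comparisons and summary statistics with figure-style significance bands.

Distribution comparisons use the two-sided Wilcoxon rank-sum test by
default (exact small-sample p-values, normal approximation with tie
correction otherwise) or Welch's unpaired t test; per-group normality is
screened with the Shapiro–Wilk test and reported alongside.  Bands:
``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for p ≤ 0.05, else
``ns`` (the 0.009–0.01 gap left by the printed coding is closed by
extending ``**`` to p < 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "summarize", "significance_band"]


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    medians: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    normality_p_per_group: tuple[float, float]
    test_name: str
    statistic: float
    p_value: float
    significance_band: Literal["ns", "*", "**", "***"]


def significance_band(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def summarize(sample) -> tuple[float, float, float]:
    """(median, mean, sd) with the n−1 sd denominator.

    For a single observation the sd is undefined; it is reported as 0.0
    (degenerate-sample convention, flagged in the log by callers that care).
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.median(x)), float(np.mean(x)), sd


def compare_groups(
    a,
    b,
    test: Literal["rank_sum", "welch_t"] = "rank_sum",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided comparison of two samples.

    ``rank_sum``: Wilcoxon rank-sum (Mann–Whitney U backend; exact null
    distribution when both n ≤ 25 and no ties).  ``welch_t``: Welch's
    unpaired t test.  Each group is screened for normality with
    Shapiro–Wilk and the p-values reported; both samples need n ≥ 3.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least 3 observations")
    norm_a = float(sps.shapiro(xa).pvalue) if np.ptp(xa) > 0 else math.nan
    norm_b = float(sps.shapiro(xb).pvalue) if np.ptp(xb) > 0 else math.nan
    if test == "rank_sum":
        method = "exact" if (xa.size <= 25 and xb.size <= 25 and _no_ties(xa, xb)) else "asymptotic"
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        name = "two-sided Wilcoxon rank-sum"
    elif test == "welch_t":
        res = sps.ttest_ind(xa, xb, equal_var=False)
        name = "Welch's unpaired t test (two-sided)"
    else:
        raise ValueError("test must be 'rank_sum' or 'welch_t'")
    p = float(res.pvalue)
    return GroupComparison(
        group_labels=labels,
        n_per_group=(int(xa.size), int(xb.size)),
        medians=(float(np.median(xa)), float(np.median(xb))),
        means=(float(np.mean(xa)), float(np.mean(xb))),
        sds=(summarize(xa)[2], summarize(xb)[2]),
        normality_p_per_group=(norm_a, norm_b),
        test_name=name,
        statistic=float(res.statistic),
        p_value=p,
        significance_band=significance_band(p),
    )


def _no_ties(xa: np.ndarray, xb: np.ndarray) -> bool:
    both = np.concatenate([xa, xb])
    return np.unique(both).size == both.size
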