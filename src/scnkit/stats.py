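"""Demographic and behavioural statistics for the cohort description.

Covers the between-group tests typically reported for a two-group cohort
table (pooled two-sample t from summary statistics, 2x2 chi-square without
continuity correction) and the Pearson correlation of per-subject thickness
change with behavioural scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedStatisticError",
    "GroupSummary",
    "TTestResult",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "behavior_correlation",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for these inputs."""


@dataclass(frozen=True)
class GroupSummary:
    """Summary (n, mean, sd) of one group, as printed in a demographics table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise UndefinedStatisticError("group summary requires n >= 2")
        if self.sd < 0:
            raise UndefinedStatisticError("sd must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t_from_summary(a: GroupSummary, b: GroupSummary, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test from group summaries.

    Pooled-variance by default (the conventional "two sample t-test" of a
    demographics table); Welch's unequal-variance form behind the flag.
    """
    if a.sd == 0 and b.sd == 0:
        raise UndefinedStatisticError("both group SDs are zero; t undefined")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return TTestResult(t=float(t), df=float(df), p=float(p))


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    Returns (chi2, df, p). Raises if any margin is zero (expected counts
    undefined).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise UndefinedStatisticError("counts must be a 2x2 table")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise UndefinedStatisticError("counts must be non-negative integers")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square undefined with a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(c, correction=False)
    return float(chi2), int(dof), float(p)


def behavior_correlation(delta_thickness, score) -> tuple[float, float]:
    """Pearson correlation of per-subject thickness change with a score.

    Returns (r, two-sided p from the exact t transform). Requires n >= 4
    and non-degenerate variance in both vectors.
    """
    x = np.asarray(delta_thickness, dtype=float)
    y = np.asarray(score, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedStatisticError("inputs must be equal-length vectors")
    if x.size < 4:
        raise UndefinedStatisticError("correlation requires n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedStatisticError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero-variance input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
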