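"""Thin named wrappers around the classical tests used downstream.

All tests are two-sided.  Welch's t uses the Welch-Satterthwaite degrees
of freedom; the paired t flags the degenerate exact-offset case (zero
variance of the within-pair differences) instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    flag: str | None = None


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t needs >= 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(res.df))


def paired_t(x, y) -> TestResult:
    """Paired-sample t-test; exact-offset pairs are flagged, not crashed."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired t needs matched samples of length >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        # constant offset: the statistic is +-inf (or 0/0 for zero offset)
        mean = float(d.mean())
        stat = np.inf * np.sign(mean) if mean != 0 else 0.0
        return TestResult(stat, 0.0 if mean != 0 else 1.0,
                          float(len(d) - 1), flag="exact_offset")
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(len(d) - 1))


def fisher_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table."""
    odds, p = sps.fisher_exact(np.asarray(table, dtype=int),
                               alternative="two-sided")
    return TestResult(float(odds), float(p))


def pearson(x, y) -> TestResult:
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return TestResult(float(r), float(p))


def spearman(x, y) -> TestResult:
    r, p = sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return TestResult(float(r), float(p))
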