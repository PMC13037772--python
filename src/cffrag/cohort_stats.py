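"""Nonparametric group comparisons and agreement analyses for cohort features.

Thin, opinionated wrappers over scipy.stats that fix the conventions used
throughout the package: two-sided p-values, midranks for ties, exact
Mann-Whitney enumeration for small untied samples, and linear-interpolation
quantiles for the median/IQR summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "PairedResult",
    "FisherResult",
    "mann_whitney",
    "paired_difference_test",
    "fisher_exact",
    "spearman",
    "linear_agreement",
    "iqr",
]

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined n (no ties)


def iqr(values) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q3 - q1)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    u: float
    p_value: float
    method: str


def mann_whitney(a, b, name_a: str = "A", name_b: str = "B") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with median/IQR summaries.

    U is the first group's statistic from midrank sums.  The p-value is exact
    (full enumeration) when n1 + n2 <= 12 with no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        name_a, name_b, a.size, b.size,
        float(np.median(a)), float(np.median(b)), iqr(a), iqr(b),
        float(res.statistic), float(res.pvalue), method,
    )


@dataclass
class PairedResult:
    statistic: float
    p_value: float
    kind: str
    n: int
    flags: set[str] = field(default_factory=set)


def paired_difference_test(x, y, kind: str = "t") -> PairedResult:
    """Two-sided paired comparison: paired t test or Wilcoxon signed-rank.

    All-zero differences give statistic 0, p = 1, flagged ``all_zero``; a
    constant nonzero shift with zero spread makes the t statistic undefined
    and is flagged ``degenerate`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    flags: set[str] = set()
    if np.all(d == 0):
        return PairedResult(0.0, 1.0, kind, d.size, {"all_zero"})
    if kind == "t":
        if d.size < 2:
            raise ValueError("paired t test needs n >= 2")
        if np.std(d, ddof=1) == 0:
            return PairedResult(np.nan, np.nan, kind, d.size, {"degenerate"})
        res = stats.ttest_rel(x, y)
        return PairedResult(float(res.statistic), float(res.pvalue), kind, d.size, flags)
    if kind == "wilcoxon":
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return PairedResult(float(res.statistic), float(res.pvalue), kind, d.size, flags)
    raise ValueError("kind must be 't' or 'wilcoxon'")


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The reported odds ratio is the sample (cross-product) ratio ad/bc; the
    p-value sums hypergeometric probabilities no larger than the observed
    table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(float(odds), float(p))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class LinearAgreement:
    slope: float
    intercept: float
    r_squared: float


def linear_agreement(x, y) -> LinearAgreement:
    """Ordinary least-squares fit of an assay quantity on a reference one.

    Used for qPCR-vs-fluorometry agreement: slope near 1 and intercept near 0
    mean the assay tracks the reference without systematic offset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linear agreement needs n >= 3")
    if np.unique(x).size == 1:
        raise ValueError("reference values are constant; slope undefined")
    res = stats.linregress(x, y)
    return LinearAgreement(float(res.slope), float(res.intercept), float(res.rvalue**2))
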