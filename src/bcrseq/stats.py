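"""Statistical tests and multiple-testing correction for repertoire comparisons.

Thin, contract-checked wrappers around scipy: two-sample Kolmogorov-Smirnov
(CDR3 length distributions), Pearson chi-square without continuity
correction (amino-acid and gene usage), Wilcoxon signed rank (paired isotype
fractions against zero), Kruskal-Wallis (healthy vs infected gene usage),
and Benjamini-Hochberg step-up adjustment.  Two-sided p-values throughout;
corrected p < 0.05 (strict) is the significance rule used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return p < ALPHA


def ks_test(x, y, method: str = "auto") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup |F1 - F2|)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ks_test requires non-empty samples")
    res = sps.ks_2samp(x, y, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "KS",
                      len(x), len(y))


def chi2_test(observed) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table.

    No Yates continuity correction.  Zero expected cells are an error — pool
    sparse categories before testing.
    """
    obs = np.asarray(observed, float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("chi2_test needs a 2-D table of non-negative counts")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero row/column sums give zero expected cells; "
                         "pool categories before testing")
    stat, p, _dof, _exp = sps.chi2_contingency(obs, correction=False)
    return TestResult(float(stat), float(p), "chi2", int(obs.sum()))


def wilcoxon_signed_rank(d, mu0: float = 0.0,
                         alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test of paired differences against ``mu0``.

    Zero differences are discarded; ties get mean ranks.  Exact p-values for
    n <= 25 without ties, normal approximation otherwise.
    """
    d = np.asarray(d, float) - mu0
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    method = "exact" if (len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)) \
        else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_signed_rank", len(d))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups (tie-corrected)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # identical groups: H is exactly 0, p = 1 (scipy raises on all-tied data)
        return TestResult(0.0, 1.0, "kruskal_wallis",
                          len(groups[0]), len(groups[1]))
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), "kruskal_wallis",
                      len(groups[0]), len(groups[1]))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def bh_rejections(p, alpha: float = ALPHA) -> int:
    """Number of rejections under classic BH step-up at level ``alpha``."""
    p = np.sort(np.asarray(p, float))
    m = len(p)
    below = np.flatnonzero(p <= alpha * np.arange(1, m + 1) / m)
    return int(below[-1] + 1) if len(below) else 0
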