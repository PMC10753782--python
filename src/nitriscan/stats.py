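"""The statistical tests used across the comparative analysis.

All tests are two-sided.  The rank-sum test is computed exactly (permutation
null) for small tie-free samples and by the tie-corrected normal
approximation otherwise; group comparisons pair a Kruskal-Wallis omnibus with
Dunn's post-hoc z tests (Bonferroni-adjusted), with classical one-way ANOVA
also available since survey papers often name ANOVA while applying Dunn's
method.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    exact: bool = False
    extra: dict = field(default_factory=dict)


_EXACT_MAX_N = 16


def _has_ties(x, y) -> bool:
    pooled = list(x) + list(y)
    return len(set(pooled)) < len(pooled)


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    ``mode='auto'`` uses the exact permutation distribution when
    n_x + n_y <= 16 and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise; 'exact' and
    'normal_approx' force the respective method.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if mode == "auto":
        exact = (x.size + y.size) <= _EXACT_MAX_N and not _has_ties(x, y)
    elif mode == "exact":
        if _has_ties(x, y):
            raise ValueError("exact mode requires tie-free data")
        exact = True
    elif mode == "normal_approx":
        exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                      method=f"Mann-Whitney ({method})",
                      n=(int(x.size), int(y.size)), exact=exact)


def dunn_pairwise(groups: list[np.ndarray], labels: list[str] | None = None) -> list[TestResult]:
    """Dunn's z post-hoc comparisons on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)).
    """
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    m = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / groups[i].size + 1.0 / groups[j].size)
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(TestResult(statistic=float(z), p_value=float(min(p_raw * m, 1.0)),
                              method="Dunn (Bonferroni)",
                              n=(int(groups[i].size), int(groups[j].size)),
                              extra={"pair": (labels[i], labels[j]),
                                     "p_raw": float(p_raw)}))
    return out


def kruskal_dunn(groups, labels: list[str] | None = None) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus (tie-corrected H) plus Dunn pairwise results."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if all(np.all(g == groups[0][0]) for g in groups):
        # all observations identical: H = 0 by convention, no evidence
        omnibus = TestResult(0.0, 1.0, "Kruskal-Wallis", tuple(g.size for g in groups))
    else:
        h, p = sps.kruskal(*groups)
        omnibus = TestResult(float(h), float(p), "Kruskal-Wallis",
                             tuple(int(g.size) for g in groups))
    return omnibus, dunn_pairwise(groups, labels)


def anova_oneway(groups) -> TestResult:
    """Classical one-way ANOVA F test."""
    groups = [np.asarray(g, float) for g in groups]
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), float(p), "one-way ANOVA",
                      tuple(int(g.size) for g in groups))


def t_test(x, y, welch: bool = False) -> TestResult:
    """Two-sample t test; classic Student's (pooled variance) by default."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    name = "Welch t" if welch else "Student t"
    return TestResult(float(t), float(p), name, (int(x.size), int(y.size)))


def pearson(x, y) -> TestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "Pearson r", (int(x.size),))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (Pearson on midranks), p via t transform."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "Spearman rho", (int(x.size),))
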