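"""Rank-based comparison of simulated survival across areas and life stages.

The foraging simulation yields per-replicate percentage survival; group
differences (by focal area, or by life stage within an area) are assessed
non-parametrically — survival percentages are bounded and strongly
non-normal.  Provides the Wilcoxon rank-sum test, the Kruskal-Wallis test
and Dunn's post hoc pairwise comparisons with multiplicity adjustment.

Tie handling uses midranks throughout with the standard tie corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_survival",
]


@dataclass
class TestResult:
    comparison: str
    statistic: float
    statistic_name: str
    p_unadjusted: float
    p_adjusted: float | None = None
    df: int | None = None
    method: str = ""
    degenerate: bool = False

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> bool:
        p = self.p_adjusted if (adjusted and self.p_adjusted is not None) else self.p_unadjusted
        return p < alpha


def _tie_correction_sum(pooled: np.ndarray) -> float:
    """sum of (t^3 - t) over tied groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_rank_sum(
    a, b, exact_threshold: int = 20
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    The reported statistic W is the rank sum of the first sample minus its
    minimum, i.e. the Mann-Whitney U of sample ``a`` (the convention of R's
    wilcox.test).  Small tie-free samples (both sizes <= exact_threshold)
    use exact enumeration of the permutation distribution; otherwise the
    normal approximation with midrank tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    degenerate = np.unique(pooled).size == 1
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    U = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if degenerate:
        return TestResult(
            comparison="a vs b", statistic=U, statistic_name="W",
            p_unadjusted=1.0, method="degenerate (all values identical)",
            degenerate=True,
        )
    if not has_ties and n1 <= exact_threshold and n2 <= exact_threshold:
        # exact permutation distribution of U by dynamic enumeration
        p = _exact_rank_sum_p(U, n1, n2)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        N = n1 + n2
        tie = _tie_correction_sum(pooled)
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var <= 0:
            p, method = 1.0, "degenerate variance"
        else:
            z = (U - mu - np.sign(U - mu) * 0.5) / np.sqrt(var)  # continuity corr.
            p = float(2 * stats.norm.sf(abs(z)))
            method = "normal approximation, tie-corrected"
    return TestResult(
        comparison="a vs b", statistic=U, statistic_name="W",
        p_unadjusted=min(p, 1.0), method=method, degenerate=degenerate,
    )


def _exact_rank_sum_p(U: float, n1: int, n2: int) -> float:
    """Two-sided exact p-value of the Mann-Whitney U statistic (no ties).

    Counts rank assignments by the classic partition recurrence: c[n1][u] =
    number of ways to choose n1 ranks with U statistic u.
    """
    max_u = n1 * n2
    # f[k][u]: ways to pick k of the pooled ranks giving U=u
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            # adding rank i as the k-th chosen element contributes (i - k) to U
            add = i - k
            if add > max_u:
                continue
            f[k, add:] += f[k - 1, : max_u + 1 - add]
    total = comb(n1 + n2, n1)
    probs = f[n1] / total
    u = int(round(U))
    p_low = probs[: u + 1].sum()
    p_high = probs[u:].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test with midrank tie correction, df = k - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        H += r.sum() ** 2 / g.size
        start += g.size
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    tie = _tie_correction_sum(pooled)
    denom = 1.0 - tie / (N**3 - N)
    df = len(groups) - 1
    if denom <= 0:  # every observation identical
        return TestResult(
            comparison="all groups", statistic=0.0, statistic_name="H",
            p_unadjusted=1.0, df=df, method="degenerate (all values identical)",
            degenerate=True,
        )
    H /= denom
    p = float(stats.chi2.sf(H, df))
    return TestResult(
        comparison="all groups", statistic=float(H), statistic_name="H",
        p_unadjusted=p, df=df, method="chi-square approximation, tie-corrected",
    )


def dunn_posthoc(
    groups: dict, adjust_method: str = "holm"
) -> list[TestResult]:
    """Dunn's pairwise post hoc comparisons after Kruskal-Wallis.

    ``groups`` maps label -> sample.  Z_ij = (mean rank_i - mean rank_j) /
    sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)) with T the tie
    correction sum.  ``adjust_method``: "holm" (default), "bonferroni" or
    "bh" (Benjamini-Hochberg).
    """
    method_map = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}
    if adjust_method not in method_map:
        raise ValueError(f"unknown adjustment {adjust_method!r}; use {sorted(method_map)}")
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([samples[k] for k in labels])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in labels:
        n = samples[k].size
        mean_rank[k] = ranks[start : start + n].mean()
        start += n
    tie = _tie_correction_sum(pooled)
    base_var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))

    results = []
    for i, j in combinations(labels, 2):
        ni, nj = samples[i].size, samples[j].size
        se = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = 0.0 if se == 0 else (mean_rank[i] - mean_rank[j]) / se
        p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
        results.append(
            TestResult(
                comparison=f"{i}-{j}", statistic=float(z), statistic_name="Z",
                p_unadjusted=p, method=f"Dunn, {adjust_method}-adjusted",
                degenerate=se == 0,
            )
        )
    raw = [r.p_unadjusted for r in results]
    adj = multipletests(raw, method=method_map[adjust_method])[1]
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def compare_survival(
    table: pd.DataFrame,
    by: str = "stage",
    value_col: str = "survival_pct",
    adjust_method: str = "holm",
) -> pd.DataFrame:
    """Tidy Kruskal-Wallis + Dunn analysis of a per-replicate survival table.

    ``table`` needs columns ``by`` and ``value_col``.  Returns one row for
    the omnibus test plus one per pairwise comparison.
    """
    if by not in table.columns or value_col not in table.columns:
        raise ValueError(f"table must have columns {by!r} and {value_col!r}")
    groups = {
        str(k): g[value_col].to_numpy() for k, g in table.groupby(by, sort=True)
    }
    rows = []
    kw = kruskal_wallis(list(groups.values()))
    rows.append(
        {
            "comparison": "omnibus",
            "statistic": kw.statistic,
            "statistic_name": kw.statistic_name,
            "df": kw.df,
            "p_unadjusted": kw.p_unadjusted,
            "p_adjusted": np.nan,
        }
    )
    for r in dunn_posthoc(groups, adjust_method=adjust_method):
        rows.append(
            {
                "comparison": r.comparison,
                "statistic": r.statistic,
                "statistic_name": r.statistic_name,
                "df": np.nan,
                "p_unadjusted": r.p_unadjusted,
                "p_adjusted": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
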