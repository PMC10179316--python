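"""Nonparametric test battery: Friedman-on-ranks with SNK post hoc,
Wilcoxon signed-rank, Mann-Whitney rank-sum, and Kruskal-Wallis with Dunn's
method.

All tests are rank-based (invariant under strictly monotone transforms of
the data) and use mid-ranks for ties.  Exact null distributions for the
signed-rank and rank-sum statistics are computed by dynamic programming at
small n; large samples use the normal approximation with tie and continuity
corrections.  The SNK post hoc follows the classic rank-sum formulation:
conditions ordered by rank sum, stepwise studentized-range tests with the
standard error sqrt(n*k*(k+1)/12), and non-significant spans blocking their
inner comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "TestResult",
    "friedman_ranks",
    "snk_posthoc_ranks",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "kruskal_dunn",
    "ranksum_tests",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n: int
    details: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Friedman


def friedman_ranks(block_matrix) -> TestResult:
    """Friedman repeated-measures ANOVA on ranks (chi-square statistic).

    `block_matrix` is n subjects x k conditions with no missing cells.
    Within-subject mid-ranks; statistic
    chi2 = [12 / (n k (k+1))] * sum R_j^2 - 3 n (k+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); p from chi2_{k-1}.
    """
    X = np.asarray(block_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("need an n x k block matrix")
    n, k = X.shape
    if n < 2 or k < 3:
        raise ValueError("need at least 2 subjects and 3 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not supported (complete blocks only)")

    ranks = sst.rankdata(X, axis=1)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    ties = sum(_tie_term(row) for row in X)
    C = 1.0 - ties / (n * k * (k**2 - 1))
    if C <= 0:  # every block fully tied
        return TestResult("friedman", 0.0, 1.0, n, {"k": k, "rank_sums": R})
    chi2 /= C
    p = float(sst.chi2.sf(chi2, k - 1))
    return TestResult("friedman", float(chi2), p, n, {"k": k, "rank_sums": R})


def _q_crit(alpha: float, span: int) -> float:
    """Studentized-range critical value with infinite error df."""
    q = sst.studentized_range.ppf(1.0 - alpha, span, np.inf)
    if not np.isfinite(q):  # older scipy: fall back to a huge df
        q = sst.studentized_range.ppf(1.0 - alpha, span, 1e6)
    return float(q)


def snk_posthoc_ranks(block_matrix, alpha: float = 0.05, labels=None) -> pd.DataFrame:
    """Student-Newman-Keuls stepdown on Friedman rank sums.

    Conditions are ordered by rank sum; the range statistic
    q = (R_max - R_min) / sqrt(n k (k+1) / 12) is compared to the
    studentized-range critical value at the pair's span; a non-significant
    span blocks all comparisons nested inside it.
    """
    X = np.asarray(block_matrix, dtype=float)
    n, k = X.shape
    if k < 3:
        raise ValueError("SNK needs at least 3 conditions")
    labels = list(labels) if labels is not None else [f"c{j}" for j in range(k)]
    ranks = sst.rankdata(X, axis=1)
    R = ranks.sum(axis=0)
    se = np.sqrt(n * k * (k + 1) / 12.0)

    order = np.argsort(R)  # ascending rank sums
    ns_blocks: list = []
    rows = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            lo, hi = order[i], order[j]
            blocked = any(bi <= i and j <= bj for bi, bj in ns_blocks)
            q = (R[hi] - R[lo]) / se
            qc = _q_crit(alpha, span)
            sig = (not blocked) and q > qc
            if not blocked and not sig:
                ns_blocks.append((i, j))
            rows.append(
                {
                    "a": labels[lo],
                    "b": labels[hi],
                    "span": span,
                    "q": float(q),
                    "q_crit": qc,
                    "blocked": blocked,
                    "significant": bool(sig),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_cdf(ranks2: np.ndarray):
    """Exact distribution of 2*W (sum of positive doubled ranks) by DP."""
    total = int(ranks2.sum())
    f = np.zeros(total + 1)
    f[0] = 1.0
    for r in ranks2:
        g = f.copy()
        g[r:] += f[: total + 1 - r]
        f = g
    f /= f.sum()
    return f  # pmf over 0..total of 2W


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test for paired samples (or one sample vs 0).

    Zero differences are dropped (counted in details).  W is the sum of the
    ranks of positive differences.  Exact p by enumeration for n <= 25 (ties
    handled through doubled mid-ranks), else normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if y is not None and len(x) != len(d):
        raise ValueError("paired samples must have equal length")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(
            "wilcoxon", 0.0, 1.0, 0, {"degenerate": True, "n_zero": n_zero}
        )
    ranks = sst.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_cdf(ranks2)
        w2 = int(round(2 * w_pos))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[w2])
        p_ge = float(pmf[w2:].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            z = (w_pos - mu - 0.5) / sd
            p = float(sst.norm.sf(z))
        elif alternative == "less":
            z = (w_pos - mu + 0.5) / sd
            p = float(sst.norm.cdf(z))
        else:
            z = (w_pos - mu - np.sign(w_pos - mu) * 0.5) / sd
            p = float(2 * sst.norm.sf(abs(z)))
        method = "normal"
    return TestResult(
        "wilcoxon",
        w_pos,
        min(1.0, p),
        n,
        {"method": method, "n_zero": n_zero, "alternative": alternative},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def _ranksum_pmf(N: int, m: int):
    """Exact pmf of the rank sum of an m-subset of ranks 1..N (no ties)."""
    max_sum = m * (2 * N - m + 1) // 2
    f = np.zeros((m + 1, max_sum + 1))
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(m, r), 0, -1):
            f[j, r:] += f[j - 1, : max_sum + 1 - r]
    pmf = f[m]
    return pmf / pmf.sum()


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney rank-sum test for two independent samples.

    U counts pairs where an x-observation exceeds a y-observation (ties as
    half).  Exact p for combined N <= 25 without ties; otherwise normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    N = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sst.rankdata(combined)
    R1 = float(ranks[:n1].sum())
    U = R1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(combined)) < N
    if N <= 25 and not has_ties:
        pmf = _ranksum_pmf(N, n1)
        r1 = int(round(R1))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[r1])
        p_ge = float(pmf[r1:].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((N + 1) - _tie_term(combined) / (N * (N - 1)))
        sd = np.sqrt(var)
        if alternative == "greater":
            z = (U - mu - 0.5) / sd
            p = float(sst.norm.sf(z))
        elif alternative == "less":
            z = (U - mu + 0.5) / sd
            p = float(sst.norm.cdf(z))
        else:
            z = (U - mu - np.sign(U - mu) * 0.5) / sd if U != mu else 0.0
            p = float(2 * sst.norm.sf(abs(z)))
        method = "normal"
    return TestResult(
        "mann-whitney",
        float(U),
        min(1.0, p),
        N,
        {"method": method, "n1": n1, "n2": n2, "alternative": alternative},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def kruskal_dunn(
    groups, alpha: float = 0.05, adjust: str | None = None, labels=None
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z post hoc.

    Dunn's z uses mean ranks and the pairwise standard error
    sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with T = sum(t^3 - t)/(12(N-1)).
    Pairwise p-values are unadjusted by default; `adjust` may be
    "bonferroni" or "sidak".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    labels = list(labels) if labels is not None else [f"g{j}" for j in range(len(groups))]
    sizes = np.array([len(g) for g in groups])
    N = int(sizes.sum())
    combined = np.concatenate(groups)
    ranks = sst.rankdata(combined)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array(
        [ranks[edges[j] : edges[j + 1]].sum() for j in range(len(groups))]
    )

    H = 12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (N + 1)
    tie = _tie_term(combined)
    C = 1.0 - tie / (N**3 - N)
    H = H / C if C > 0 else 0.0
    p = float(sst.chi2.sf(H, len(groups) - 1)) if C > 0 else 1.0

    mean_ranks = rank_sums / sizes
    T = tie / (12.0 * (N - 1))
    rows = []
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            praw = float(2 * sst.norm.sf(abs(z)))
            if adjust == "bonferroni":
                padj = min(1.0, praw * n_pairs)
            elif adjust == "sidak":
                padj = 1.0 - (1.0 - praw) ** n_pairs
            elif adjust is None:
                padj = praw
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "z": float(z),
                    "pvalue": padj,
                    "significant": padj < alpha,
                }
            )
    pairwise = pd.DataFrame(rows)
    return TestResult(
        "kruskal-wallis", float(H), p, N, {"k": k, "adjust": adjust}, pairwise
    )


def ranksum_tests(groups, variant: str = "mann_whitney", **kwargs) -> TestResult:
    """Dispatch between the two between-group rank tests."""
    if variant == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        return mann_whitney(groups[0], groups[1], **kwargs)
    if variant == "kruskal_dunn":
        return kruskal_dunn(groups, **kwargs)
    raise ValueError(f"unknown variant {variant!r}")
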