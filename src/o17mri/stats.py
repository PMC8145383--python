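"""Nonparametric group statistics for small cohorts.

Small animal cohorts (n = 4 per group) call for exact tests: the exact
two-sided Mann-Whitney U (full enumeration of group labelings), the
Friedman test for repeated measures across model variants (exact by
enumeration of within-subject rank permutations at small k, n), Dunn's
rank-based post hoc comparisons, and the Pearson correlation.

Ties are handled with mid-ranks throughout.  Exact p-values are rational:
integer counts over the total number of equally likely configurations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_exact",
    "friedman_test",
    "dunn_posthoc",
    "pearson_corr",
]


@dataclass
class GroupComparison:
    statistic: float
    p_two_sided: float
    method: str
    n: tuple[int, ...]
    exact: bool = True
    extra: dict = field(default_factory=dict)


def mann_whitney_exact(x, y, exact_max_n: int = 12) -> GroupComparison:
    """Two-sided Mann-Whitney U test, exact for small samples.

    For combined n <= ``exact_max_n`` the p-value is computed by
    enumerating all C(n1+n2, n1) group labelings of the pooled mid-ranks;
    the two-sided p is 2 * min(lower tail, upper tail), capped at 1
    (GraphPad-compatible for untied small samples).  Larger samples fall
    back to the tie-corrected normal approximation (``exact=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_stat = min(u1, u2)

    if n1 + n2 <= exact_max_n:
        total = math.comb(n1 + n2, n1)
        n_le = n_ge = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = ranks[list(combo)].sum()
            if r <= r1 + 1e-9:
                n_le += 1
            if r >= r1 - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return GroupComparison(
            statistic=u_stat,
            p_two_sided=p,
            method="mann_whitney_exact",
            n=(n1, n2),
            exact=True,
            extra={"U1": u1, "U2": u2},
        )

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        statistic=u_stat,
        p_two_sided=float(res.pvalue),
        method="mann_whitney_normal_approx",
        n=(n1, n2),
        exact=False,
        extra={"U1": u1, "U2": u2},
    )


def _friedman_chi(rank_sums: np.ndarray, n: int, k: int) -> float:
    """Friedman chi-square statistic from column rank sums."""
    return 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)


def friedman_test(
    matrix, exact_max_k: int = 4, exact_max_n: int = 6
) -> GroupComparison:
    """Friedman test on a complete subjects x conditions matrix.

    Rows are subjects, columns are conditions; values are ranked within
    each subject (mid-ranks on ties).  For k <= 4 conditions and n <= 6
    subjects the null distribution is enumerated exactly over the (k!)^n
    equally likely within-subject rank permutations (via a rank-sum
    convolution, so the cost is polynomial); otherwise the chi-square
    approximation is used (``exact=False``).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2D with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing cells)")
    n, k = m.shape
    row_ranks = np.vstack([sps.rankdata(row) for row in m])
    rank_sums = row_ranks.sum(axis=0)
    chi = _friedman_chi(rank_sums, n, k)

    if k <= exact_max_k and n <= exact_max_n:
        # Convolve the distribution of the column rank-sum vector over
        # subjects.  Ranks are multiples of 1/2; scale by 2 to use ints.
        kfact = math.factorial(k)
        states: dict[tuple[int, ...], int] = {(0,) * k: 1}
        for row in row_ranks:
            doubled = np.rint(2 * row).astype(int)
            new_states: dict[tuple[int, ...], int] = {}
            for perm in itertools.permutations(doubled):
                for state, cnt in states.items():
                    key = tuple(s + p for s, p in zip(state, perm))
                    new_states[key] = new_states.get(key, 0) + cnt
            states = new_states
        total = kfact**n
        n_ge = 0
        for state, cnt in states.items():
            chi_perm = _friedman_chi(np.asarray(state) / 2.0, n, k)
            if chi_perm >= chi - 1e-9:
                n_ge += cnt
        p = n_ge / total
        return GroupComparison(
            statistic=chi,
            p_two_sided=p,
            method="friedman",
            n=(n, k),
            exact=True,
            extra={"rank_sums": rank_sums.tolist()},
        )

    res = sps.friedmanchisquare(*[m[:, j] for j in range(k)])
    return GroupComparison(
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        method="friedman_chi2_approx",
        n=(n, k),
        exact=False,
        extra={"rank_sums": rank_sums.tolist()},
    )


def dunn_posthoc(
    matrix,
    comparisons: list[tuple[int, int]] | None = None,
    labels: list[str] | None = None,
) -> dict[tuple, GroupComparison]:
    """Dunn's rank-based post hoc comparisons after a Friedman test.

    For each requested pair (i, j) of conditions the z statistic is the
    difference of mean within-subject ranks over sqrt(k(k+1)/(6n)); the
    two-sided normal p is multiplied by the number of comparisons in the
    family (Bonferroni-style), capped at 1.  The family defaults to all
    pairs; pass ``comparisons`` to restrict it (e.g. each model against a
    reference model).  With k = 2 the family has size 1 and the result is
    the unadjusted two-condition rank comparison.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if comparisons is None:
        comparisons = list(itertools.combinations(range(k), 2))
    for i, j in comparisons:
        if not (0 <= i < k and 0 <= j < k):
            raise ValueError(f"comparison ({i}, {j}) references an unknown condition")
    row_ranks = np.vstack([sps.rankdata(row) for row in m])
    mean_ranks = row_ranks.mean(axis=0)
    scale = math.sqrt(k * (k + 1) / (6.0 * n))
    family = len(comparisons)

    out: dict[tuple, GroupComparison] = {}
    for i, j in comparisons:
        z = (mean_ranks[i] - mean_ranks[j]) / scale
        p_unadj = 2.0 * sps.norm.sf(abs(z))
        key = (labels[i], labels[j]) if labels is not None else (i, j)
        out[key] = GroupComparison(
            statistic=float(z),
            p_two_sided=float(min(1.0, family * p_unadj)),
            method="dunn",
            n=(n, k),
            exact=False,
            extra={"p_unadjusted": float(p_unadj), "family_size": family},
        )
    return out


def pearson_corr(x, y) -> GroupComparison:
    """Pearson correlation with a two-sided p-value via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return GroupComparison(
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        method="pearson",
        n=(x.size,),
        exact=False,
    )
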