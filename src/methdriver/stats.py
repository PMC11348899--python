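"""Shared statistical primitives.

Two-sided Wilcoxon rank-sum (Mann-Whitney) testing with an exact
permutation branch for small groups, Benjamini-Hochberg FDR control, and
the rank-based AUC.  The exact branch enumerates every assignment of the
combined sample to the two groups (mid-ranks for ties) and is used
whenever both groups have at most ``EXACT_MAX_GROUP`` members; larger
designs use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# Both groups at or below this size -> exact enumeration (C(16,8)=12,870
# assignments at the limit); above it, normal approximation.
EXACT_MAX_GROUP = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y, mid-ranks for ties (ties count half)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    p = P(|U* - n1*n2/2| >= |U_obs - n1*n2/2|) over all C(n1+n2, n1)
    equally likely assignments of the observed values to group labels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    obs_dev = abs(u_obs - mu)
    idx = np.fromiter(
        (i for comb in combinations(range(n1 + n2), n1) for i in comb),
        dtype=np.intp,
    ).reshape(-1, n1)
    u_all = ranks[idx].sum(axis=1) - offset
    # tolerance guards float mid-rank arithmetic at the boundary
    hits = np.abs(u_all - mu) >= obs_dev - 1e-9
    return float(hits.mean())


def ranksum_asymptotic_p(
    x: np.ndarray, y: np.ndarray, axis: int = -1
) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p with continuity correction."""
    res = sps.mannwhitneyu(
        x, y, axis=axis, method="asymptotic", use_continuity=True,
        alternative="two-sided",
    )
    return np.asarray(res.pvalue, dtype=float)


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p for a single pair of samples.

    Exact enumeration when both groups have <= EXACT_MAX_GROUP members
    (mid-ranks under ties), normal approximation otherwise.  Constant
    pooled samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        return ranksum_exact_p(x, y)
    return float(ranksum_asymptotic_p(x, y))


def ranksum_p_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p for matrices x (rows x n1), y (rows x n2).

    The exact/asymptotic choice is made once from the group sizes;
    degenerate (constant) rows return p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y], axis=1)
    constant = np.all(pooled == pooled[:, :1], axis=1)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        p = np.array([ranksum_exact_p(xi, yi) for xi, yi in zip(x, y)])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ranksum_asymptotic_p(x, y, axis=1)
    p = np.where(constant, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = U/(n_pos*n_neg), with tied score pairs counted half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    return _u_statistic(pos, neg) / (len(pos) * len(neg))
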