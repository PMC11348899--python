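"""Numba kernels for circular binary segmentation.

The arc statistic for a stretch x[0..n) and an arc (i, j] is the
two-sample t-like quantity

    |mean(arc) - mean(complement)| / (s_p * sqrt(1/L + 1/(n-L)))

with s_p the pooled within-part standard deviation.  A zero pooled SD
with differing part means scores +inf (an exact changepoint).  Ties in
the argmax are broken toward the lexicographically smallest (i, j).

The permutation null is evaluated sequentially with early stopping: the
scan aborts as soon as the accept/reject decision at the requested alpha
is settled (see ``sequential_perm_test``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _prefix_sums(x):
    n = x.size
    s = np.zeros(n + 1)
    q = np.zeros(n + 1)
    for k in range(n):
        s[k + 1] = s[k] + x[k]
        q[k + 1] = q[k] + x[k] * x[k]
    return s, q


@njit(cache=True)
def best_arc(x):
    """Return (stat, i, j) of the max-statistic arc (i, j], 1 <= j-i < n."""
    n = x.size
    s, q = _prefix_sums(x)
    tot = s[n]
    qtot = q[n]
    best = -1.0
    bi = 0
    bj = 0
    for i in range(n):
        for j in range(i + 1, n + 1):
            L = j - i
            if L >= n:
                break
            sa = s[j] - s[i]
            m1 = sa / L
            m2 = (tot - sa) / (n - L)
            qa = q[j] - q[i]
            ss = (qa - sa * sa / L) + (qtot - qa - (tot - sa) * (tot - sa) / (n - L))
            diff = abs(m1 - m2)
            if ss < _EPS:
                stat = np.inf if diff > 1e-9 else 0.0
            else:
                stat = diff / np.sqrt(ss / (n - 2) * (1.0 / L + 1.0 / (n - L)))
            if stat > best:
                best = stat
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _exceeds(x, target):
    """True iff some arc of x reaches statistic >= target (early exit)."""
    n = x.size
    s, q = _prefix_sums(x)
    tot = s[n]
    qtot = q[n]
    for i in range(n):
        for j in range(i + 1, n + 1):
            L = j - i
            if L >= n:
                break
            sa = s[j] - s[i]
            m1 = sa / L
            m2 = (tot - sa) / (n - L)
            qa = q[j] - q[i]
            ss = (qa - sa * sa / L) + (qtot - qa - (tot - sa) * (tot - sa) / (n - L))
            diff = abs(m1 - m2)
            if ss < _EPS:
                stat = np.inf if diff > 1e-9 else 0.0
            else:
                stat = diff / np.sqrt(ss / (n - 2) * (1.0 / L + 1.0 / (n - L)))
            if stat >= target:
                return True
    return False


@njit(cache=True)
def sequential_perm_test(x, obs, n_perm, stop_exceed, accept_after, seed):
    """Sequentially shuffle x, counting permutations whose max arc statistic
    reaches obs.  Returns (k, m): exceedance count and permutations used.

    Stops early when k reaches ``stop_exceed`` (decision 'no split' is then
    settled) or when k == 0 after ``accept_after`` permutations (p-hat =
    1/(1+m) is already below alpha).
    """
    np.random.seed(seed)
    y = x.copy()
    k = 0
    for m in range(1, n_perm + 1):
        np.random.shuffle(y)
        if _exceeds(y, obs):
            k += 1
            if k >= stop_exceed:
                return k, m
        if m >= accept_after and k == 0:
            return 0, m
    return k, n_perm
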