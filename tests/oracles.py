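"""Independent reference implementations used to check the package.

These deliberately use different algorithms from the implementation: the
alignment oracle enumerates alignments by a last-aligned-pair recursion
instead of the Gotoh matrices, the lambda oracle is a plain interval-
doubling bisection, and the ROC oracle counts true positives above each
false positive directly.
"""

from functools import lru_cache

import numpy as np


def bisect_lambda(scores, background, tol=1e-12):
    """High-precision bisection for sum p_i p_j exp(lambda s_ij) = 1."""
    s = np.asarray(scores, dtype=float)
    p = np.asarray(background, dtype=float)
    joint = p[:, None] * p[None, :]
    total = joint.sum()

    def f(lam):
        return (joint * np.exp(lam * s)).sum() - total

    hi = 1e-3
    while f(hi) < 0:
        hi *= 2.0
    lo = hi / 2.0
    while f(lo) > 0:
        lo /= 2.0
    for _ in range(500):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * hi:
            break
    return 0.5 * (lo + hi)


def brute_force_local_alignment(score_rows, subject, gap_open, gap_extend):
    """Optimal affine-gap local alignment score by last-pair recursion.

    An alignment is a non-empty monotone chain of aligned pairs; the cost of
    the jump between consecutive pairs is w(g) = gap_open + g * gap_extend
    for each sequence with g > 0 skipped residues (w(0) = 0).  This covers
    exactly the alignments reachable by the affine Smith–Waterman recursion.
    """
    l = len(score_rows)
    n = len(subject)

    def w(g):
        return 0 if g == 0 else gap_open + g * gap_extend

    @lru_cache(maxsize=None)
    def best_ending_at(i, j):
        base = int(score_rows[i][subject[j]])
        best = base
        for pi in range(i):
            for pj in range(j):
                cand = (
                    best_ending_at(pi, pj)
                    - w(i - pi - 1)
                    - w(j - pj - 1)
                    + base
                )
                if cand > best:
                    best = cand
        return best

    overall = 0
    for i in range(l):
        for j in range(n):
            overall = max(overall, best_ending_at(i, j))
    best_ending_at.cache_clear()
    return overall


def roc_n_enumeration(labels_in_rank_order, n, total_positives):
    """Direct ROC_n: t_i = TPs ranked above the i-th FP; repeat last t_i."""
    t = 0
    tis = []
    for lab in labels_in_rank_order:
        if lab == "TP":
            t += 1
        elif lab == "FP":
            tis.append(t)
    if len(tis) >= n:
        tis = tis[:n]
    else:
        filler = tis[-1] if tis else t
        tis = tis + [filler] * (n - len(tis))
    return sum(tis) / (n * total_positives)


def length_adjustment_fixed_point(m, n, N, lam, K, H, iters=200):
    """Independent fixed-point iteration for the BLAST length adjustment."""
    ell = 0.0
    for _ in range(iters):
        m_red = max(m - ell, 1.0)
        n_red = max(n - N * ell, float(N))
        new = max(0.0, np.log(K * m_red * n_red) / H)
        new = min(new, m - 1.0, (n - N) / N if n > N else 0.0)
        new = max(new, 0.0)
        if abs(new - ell) < 1e-12:
            ell = new
            break
        ell = new
    return np.floor(ell)
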