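"""Independent brute-force oracles used by the test suite.

Every oracle here is a deliberately naive re-computation (O(n·m) scans,
exhaustive enumeration, full dynamic programs) kept separate from the
library's optimized code paths.
"""

from __future__ import annotations

import numpy as np


def overlaps_any_bruteforce(qs, qe, ts, te):
    out = np.zeros(len(qs), dtype=bool)
    for i, (a, b) in enumerate(zip(qs, qe)):
        for c, d in zip(ts, te):
            if a < d and c < b:
                out[i] = True
                break
    return out


def overlap_bp_bruteforce(qs, qe, ts, te):
    out = np.zeros(len(qs), dtype=np.int64)
    for i, (a, b) in enumerate(zip(qs, qe)):
        covered = np.zeros(b - a, dtype=bool)
        for c, d in zip(ts, te):
            lo, hi = max(a, c), min(b, d)
            if lo < hi:
                covered[lo - a : hi - a] = True
        out[i] = covered.sum()
    return out


def merge_bruteforce(starts, ends):
    ivs = sorted(zip(starts, ends))
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def fdr_threshold_bruteforce(real, perm, fdr=0.05):
    """Scan every candidate threshold; min density with FDR < fdr."""
    real = np.asarray(real, dtype=float)
    perm = np.asarray(perm, dtype=float)
    passing = []
    for t in real:
        n_real = (real >= t).sum()
        n_perm = (perm >= t).sum()
        if n_real > 0 and n_perm / n_real < fdr:
            passing.append(t)
    return min(passing) if passing else None


def bmr_bruteforce(levels, mean, min_run=3):
    """Indices (start, end) of maximal runs of ≥min_run windows > mean."""
    out = []
    i = 0
    n = len(levels)
    while i < n:
        if levels[i] > mean:
            j = i
            while j + 1 < n and levels[j + 1] > mean:
                j += 1
            if j - i + 1 >= min_run:
                out.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def pwm_threshold_enumeration(pwm, p_thresh, background=None, precision=1e-9):
    """Exhaustive enumeration over all 4^L words.

    Per-position scores are snapped to the same grid the implementation
    discretizes on, so tied-word groups are identical; the enumeration
    itself (explicit sum over words) stays independent of the DP recursion.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    sc = np.log2(np.asarray(pwm) / bg[:, None])
    sc = np.round(sc / precision) * precision
    L = sc.shape[1]
    tot = np.zeros(1)
    prob = np.ones(1)
    for j in range(L):
        tot = (tot[:, None] + sc[:, j][None, :]).ravel()
        prob = (prob[:, None] * bg[None, :]).ravel()
    # group words with (numerically) identical scores: a threshold admits
    # every word scoring ≥ it, so tails accumulate per unique score
    uniq, inv = np.unique(np.round(tot, 9), return_inverse=True)
    mass = np.bincount(inv, weights=prob)
    uniq, mass = uniq[::-1], mass[::-1]
    tail = np.cumsum(mass)
    ok = tail <= p_thresh + 1e-15
    if not ok.any():
        return np.inf
    return float(uniq[ok][-1])


def smith_waterman_score(a, b, match=1, mismatch=-1, gap_first=7, gap_ext=2):
    """Full affine-gap local alignment score (pure python DP)."""
    n, m = len(a), len(b)
    neg = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - gap_first, Ei[j - 1] - gap_ext)
            Fi[j] = max(Hi1[j] - gap_first, Fi1[j] - gap_ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = max(0, Hi1[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def dtw_cost_recursive(a, b):
    """Boundary-anchored DTW cost by memoized recursion (small grids)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return abs(a[0] - b[0])
        if i == 0:
            return d(0, j - 1) + abs(a[0] - b[j])
        if j == 0:
            return d(i - 1, 0) + abs(a[i] - b[0])
        return min(d(i - 1, j - 1), d(i - 1, j), d(i, j - 1)) + abs(a[i] - b[j])

    return d(len(a) - 1, len(b) - 1)


def count_in_intervals_bruteforce(positions, starts, ends):
    return [sum(1 for p in positions if s <= p < e) for s, e in zip(starts, ends)]
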