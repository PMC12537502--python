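"""Interval algebra on 0-based half-open coordinates.

All functions operate on parallel numpy arrays of starts and ends within a
single chromosome; callers group by chromosome.  Conventions follow BED:
``[start, end)``, an insertion at position p occupies ``[p, p+1)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "overlaps_any",
    "overlap_bp",
    "nearest_gap",
    "subtract",
    "coverage_fraction",
]


def merge(starts, ends, gap: int = 0):
    """Merge overlapping (or within ``gap`` bp) intervals.

    Returns (starts, ends, cluster_id) where cluster_id maps each input
    interval (in sorted order of the output) to its merged run.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # new cluster starts where start exceeds running max end + gap
    run_max = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_max[:-1] + gap
    cid_sorted = np.cumsum(new_run) - 1
    n = cid_sorted[-1] + 1
    ms = np.zeros(n, dtype=np.int64)
    me = np.zeros(n, dtype=np.int64)
    ms[cid_sorted[new_run]] = s[new_run]
    np.maximum.at(me, cid_sorted, e)
    cid = np.empty(starts.size, dtype=np.int64)
    cid[order] = cid_sorted
    return ms, me, cid


class _SortedIntervals:
    """Preprocessed target set for repeated overlap / distance queries."""

    def __init__(self, starts, ends):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.order = order
        self.prefix_max_end = (
            np.maximum.accumulate(self.ends) if starts.size else self.ends
        )


def overlaps_any(q_starts, q_ends, t_starts, t_ends) -> np.ndarray:
    """Boolean per query: does it overlap (≥1 bp) any target interval?"""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    t = _SortedIntervals(t_starts, t_ends)
    if t.starts.size == 0 or q_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    idx = np.searchsorted(t.starts, q_ends, side="left")
    out = np.zeros(q_starts.size, dtype=bool)
    nz = idx > 0
    out[nz] = t.prefix_max_end[idx[nz] - 1] > q_starts[nz]
    return out


def overlap_bp(q_starts, q_ends, t_starts, t_ends) -> np.ndarray:
    """Total bp of each query covered by the union of the targets."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me, _ = merge(t_starts, t_ends)
    if ms.size == 0 or q_starts.size == 0:
        return np.zeros(q_starts.size, dtype=np.int64)
    # cumulative covered bp up to each merged boundary
    widths = me - ms
    cum = np.concatenate([[0], np.cumsum(widths)])

    def covered_before(pos):
        # total covered bp in [0, pos)
        i = np.searchsorted(ms, pos, side="right")  # intervals starting at/before pos
        extra = np.where(
            i > 0, np.clip(pos - ms[np.maximum(i - 1, 0)], 0, widths[np.maximum(i - 1, 0)]), 0
        )
        full = np.where(i > 0, cum[np.maximum(i - 1, 0)], 0)
        return full + extra

    return covered_before(q_ends) - covered_before(q_starts)


def nearest_gap(q_starts, q_ends, t_starts, t_ends):
    """Per query: (gap bp to nearest target, index of that target).

    Gap is 0 for overlapping/adjacent-touching intervals; targets indexed in
    their original order.  Queries with no targets get gap=-1, idx=-1.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    t_starts_a = np.asarray(t_starts, dtype=np.int64)
    t_ends_a = np.asarray(t_ends, dtype=np.int64)
    nq = q_starts.size
    if t_starts_a.size == 0:
        return np.full(nq, -1, dtype=np.int64), np.full(nq, -1, dtype=np.int64)
    gaps = np.empty(nq, dtype=np.int64)
    idxs = np.empty(nq, dtype=np.int64)
    # small-n loop is fine at the scales used (annotation-sized inputs)
    for i in range(nq):
        g = np.maximum(t_starts_a - q_ends[i], q_starts[i] - t_ends_a)
        g = np.maximum(g, 0)
        j = int(np.argmin(g))
        gaps[i] = g[j]
        idxs[i] = j
    return gaps, idxs


def subtract(a_starts, a_ends, b_starts, b_ends):
    """Set difference A \\ B as merged intervals."""
    as_, ae, _ = merge(a_starts, a_ends)
    bs, be, _ = merge(b_starts, b_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(as_, ae):
        cur = s
        while j < bs.size and be[j] <= cur:
            j += 1
        k = j
        while k < bs.size and bs[k] < e:
            if bs[k] > cur:
                out_s.append(cur)
                out_e.append(min(bs[k], e))
            cur = max(cur, be[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def coverage_fraction(q_starts, q_ends, t_starts, t_ends) -> np.ndarray:
    """Fraction of each query's span covered by the union of targets."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    bp = overlap_bp(q_starts, q_ends, t_starts, t_ends)
    width = np.maximum(q_ends - q_starts, 1)
    return bp / width
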