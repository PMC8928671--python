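"""Vectorized interval arithmetic on 0-based half-open coordinates.

All functions operate on numpy arrays of starts/ends belonging to a single
chromosome; callers are responsible for partitioning by chromosome.  Two
intervals are considered overlapping when they share at least one base,
i.e. ``a.start < b.end and b.start < a.end``.  Abutting intervals
([100,200) and [200,300)) do not overlap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_arrays",
    "spans_overlap_any",
    "points_in_intervals",
    "count_overlapping_spans",
]


def merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Fuse intervals that overlap by >=1 base.

    Returns ``(merged_starts, merged_ends, group_index)`` where
    ``group_index[i]`` is the index of the merged interval that input
    interval ``i`` was fused into (useful for label union).  Output is
    sorted and strictly non-overlapping.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # a new merged group begins where the start clears every previous end
    cummax_end = np.maximum.accumulate(e)
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] >= cummax_end[:-1]
    gid_sorted = np.cumsum(new_group) - 1
    n_groups = gid_sorted[-1] + 1
    merged_s = s[new_group]
    merged_e = np.zeros(n_groups, dtype=np.int64)
    np.maximum.at(merged_e, gid_sorted, e)
    group_index = np.empty(s.size, dtype=np.int64)
    group_index[order] = gid_sorted
    return merged_s, merged_e, group_index


def spans_overlap_any(
    qstarts: np.ndarray,
    qends: np.ndarray,
    mstarts: np.ndarray,
    mends: np.ndarray,
) -> np.ndarray:
    """Boolean per query span: does it overlap any interval of a merged set?

    ``mstarts``/``mends`` must be sorted and non-overlapping (output of
    :func:`merge_arrays`).
    """
    qstarts = np.asarray(qstarts, dtype=np.int64)
    qends = np.asarray(qends, dtype=np.int64)
    if mstarts.size == 0 or qstarts.size == 0:
        return np.zeros(qstarts.size, dtype=bool)
    # last merged interval starting strictly before the query end
    j = np.searchsorted(mstarts, qends, side="left") - 1
    hit = j >= 0
    hit[hit] = mends[j[hit]] > qstarts[hit]
    return hit


def points_in_intervals(
    points: np.ndarray, mstarts: np.ndarray, mends: np.ndarray
) -> np.ndarray:
    """Index of the merged interval containing each point, or -1.

    The merged set must be sorted and non-overlapping, so membership is
    unambiguous.
    """
    points = np.asarray(points, dtype=np.int64)
    if mstarts.size == 0 or points.size == 0:
        return np.full(points.size, -1, dtype=np.int64)
    j = np.searchsorted(mstarts, points, side="right") - 1
    inside = (j >= 0) & (points < mends[np.clip(j, 0, None)])
    return np.where(inside, j, -1)


def count_overlapping_spans(
    qstarts: np.ndarray,
    qends: np.ndarray,
    istarts: np.ndarray,
    iends: np.ndarray,
) -> np.ndarray:
    """For each target interval, count query spans overlapping it by >=1 base.

    Valid for any target set (need not be disjoint): a span [s,e) overlaps
    target [S,E) iff s < E and e > S, so the count is
    ``#{s < E} - #{e <= S}``.
    """
    s_sorted = np.sort(np.asarray(qstarts, dtype=np.int64))
    e_sorted = np.sort(np.asarray(qends, dtype=np.int64))
    lo = np.searchsorted(s_sorted, np.asarray(iends, dtype=np.int64), side="left")
    hi = np.searchsorted(e_sorted, np.asarray(istarts, dtype=np.int64), side="right")
    return lo - hi
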