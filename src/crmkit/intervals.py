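"""Exact arithmetic on 0-based half-open genomic intervals.

All functions operate per chromosome on ``(n, 2)`` integer arrays of
``[start, end)`` rows, or on dicts mapping chromosome name to such arrays.
Half-open semantics are used throughout: ``[0, 10)`` and ``[10, 20)`` abut
but do not overlap, and the length of ``[a, b)`` is ``b - a``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_array",
    "merge",
    "union_length",
    "complement",
    "intersect",
    "intersection_length",
    "count_overlapping_pairs",
    "subtract",
]


def as_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to a sorted (n, 2) int array."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("every interval must satisfy start < end")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def merge(intervals, *, min_gap: int = 0) -> np.ndarray:
    """Merge intervals that overlap (or lie within ``min_gap`` bp).

    With the default ``min_gap=0`` abutting intervals are merged into one
    covered run (union semantics); overlap of >= 1 bp always merges.
    """
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s - cur_e <= min_gap:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def union_length(intervals) -> int:
    m = merge(intervals)
    if len(m) == 0:
        return 0
    return int(np.sum(m[:, 1] - m[:, 0]))


def complement(intervals, span: tuple[int, int]) -> np.ndarray:
    """Positions of ``[span_start, span_end)`` not covered by ``intervals``."""
    lo, hi = span
    m = merge(intervals)
    out = []
    cursor = lo
    for s, e in m:
        s, e = max(s, lo), min(e, hi)
        if s >= e:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        out.append((cursor, hi))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect(a, b) -> np.ndarray:
    """Interval intersection of two merged sets (sweep line)."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersection_length(a, b) -> int:
    x = intersect(a, b)
    if len(x) == 0:
        return 0
    return int(np.sum(x[:, 1] - x[:, 0]))


def subtract(a, b) -> np.ndarray:
    """Positions covered by ``a`` but not by ``b``."""
    a = merge(a)
    if len(a) == 0:
        return a
    lo, hi = int(a[0, 0]), int(a[-1, 1])
    return intersect(a, complement(b, (lo, hi)))


def count_overlapping_pairs(a, b) -> int:
    """Number of (i, j) pairs with a[i] overlapping b[j] by >= 1 bp.

    Intervals are taken as given (not merged); duplicates count separately.
    """
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return 0
    bs = np.sort(b[:, 0])
    be = np.sort(b[:, 1])
    # b intervals overlapping [s, e): those with start < e minus those with end <= s
    n_start_before_end = np.searchsorted(bs, a[:, 1], side="left")
    n_end_before_start = np.searchsorted(be, a[:, 0], side="right")
    return int(np.sum(n_start_before_end - n_end_before_start))
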