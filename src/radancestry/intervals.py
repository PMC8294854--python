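"""Vectorized arithmetic on sorted, disjoint, 0-based half-open intervals.

Intervals are ``(m, 2)`` integer numpy arrays ``[[start, end), ...]``. All
public functions in the package normalise user input through
:func:`merge_intervals` before relying on the sorted/disjoint contract.
"""

from __future__ import annotations

import numpy as np

EMPTY = np.empty((0, 2), dtype=np.int64)


def as_intervals(iv) -> np.ndarray:
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return EMPTY.copy()
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be an (m, 2) array of [start, end)")
    return arr


def merge_intervals(iv) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals; drop empty ones."""
    arr = as_intervals(iv)
    arr = arr[arr[:, 1] > arr[:, 0]]
    if len(arr) == 0:
        return EMPTY.copy()
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    starts, ends = [arr[0, 0]], [arr[0, 1]]
    for s, e in arr[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.column_stack([starts, ends]).astype(np.int64)


def total_length(iv) -> int:
    arr = as_intervals(iv)
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two sorted disjoint interval sets (sorted, disjoint)."""
    a = as_intervals(a)
    b = as_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return EMPTY.copy()
    lo = np.searchsorted(b[:, 1], a[:, 0], side="right")
    hi = np.searchsorted(b[:, 0], a[:, 1], side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return EMPTY.copy()
    ai = np.repeat(np.arange(len(a)), counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    bi = np.arange(total) - offsets + np.repeat(lo, counts)
    starts = np.maximum(a[ai, 0], b[bi, 0])
    ends = np.minimum(a[ai, 1], b[bi, 1])
    keep = ends > starts
    return np.column_stack([starts[keep], ends[keep]])


def covered_before(iv: np.ndarray, x) -> np.ndarray:
    """Covered basepairs in [0, x) for each query x (iv sorted disjoint)."""
    x = np.asarray(x, dtype=np.int64)
    if len(iv) == 0:
        return np.zeros(x.shape, dtype=np.int64)
    starts, ends = iv[:, 0], iv[:, 1]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    i = np.searchsorted(starts, x, side="right")
    full = cum[i]
    # subtract the part of interval i-1 at/after x
    prev_end = np.where(i > 0, ends[np.maximum(i - 1, 0)], 0)
    prev_start = np.where(i > 0, starts[np.maximum(i - 1, 0)], 0)
    overhang = np.clip(prev_end - np.maximum(x, prev_start), 0, None)
    overhang = np.where(i > 0, overhang, 0)
    return (full - overhang).astype(np.int64)


def window_overlap(iv, starts, ends) -> np.ndarray:
    """Covered bp of the interval set within each window [start, end)."""
    iv = as_intervals(iv)
    c_end = covered_before(iv, ends)
    c_start = covered_before(iv, starts)
    return c_end - c_start


def in_intervals(iv, pos) -> np.ndarray:
    """Boolean mask: which positions fall inside the interval set."""
    iv = as_intervals(iv)
    pos = np.asarray(pos, dtype=np.int64)
    if len(iv) == 0:
        return np.zeros(pos.shape, dtype=bool)
    i = np.searchsorted(iv[:, 0], pos, side="right")
    inside = i > 0
    inside &= pos < iv[np.maximum(i - 1, 0), 1]
    return inside
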