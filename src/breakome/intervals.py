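"""Exact half-open interval arithmetic on integer genomic coordinates.

All functions operate on ``(N, 2)`` int64 arrays of ``[start, end)`` rows.
Inputs need not be sorted or disjoint unless stated; outputs of
:func:`merge` are sorted and disjoint, which is the normal form the rest
of the package assumes for masks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "intersect",
    "subtract",
    "total_length",
    "contains",
]


def as_intervals(pairs) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (N, 2) int64 array.

    Raises ``ValueError`` on negative-length intervals.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (N, 2) pairs")
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("negative-length interval")
    return arr


def merge(ivs: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals into normal form."""
    ivs = as_intervals(ivs)
    ivs = ivs[ivs[:, 1] > ivs[:, 0]]  # drop empties
    if len(ivs) == 0:
        return ivs
    ivs = ivs[np.lexsort((ivs[:, 1], ivs[:, 0]))]
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two interval sets, returned in normal form."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_intervals(out)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b, returned in normal form."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return as_intervals(out)


def total_length(ivs: np.ndarray) -> int:
    """Total bp covered; exact for normal-form input, merges otherwise."""
    ivs = merge(ivs)
    if len(ivs) == 0:
        return 0
    return int(np.sum(ivs[:, 1] - ivs[:, 0]))


def contains(ivs: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in a normal-form interval set."""
    ivs = merge(ivs)
    pos = np.asarray(pos, dtype=np.int64)
    if len(ivs) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(ivs[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] = pos[ok] < ivs[idx[ok], 1]
    return ok
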