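"""Small interval-arithmetic helpers on a single integer axis.

All functions work on half-open intervals ``[start, end)`` given as parallel
numpy arrays on one coordinate axis (callers map per-chromosome intervals to
the concatenated genome coordinate first, see :meth:`Genome.to_absolute`).
"""

from __future__ import annotations

import numpy as np


def merge_union(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals as a sorted, disjoint set (bookended pieces fuse)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def union_length(starts, ends) -> int:
    s, e = merge_union(starts, ends)
    return int(np.sum(e - s))


class CoverageIndex:
    """Prefix-sum index over a fixed interval set for fast base-overlap queries.

    Built once from a (possibly overlapping) interval set; ``covered(a, b)``
    then returns, for each query interval, the number of bases of ``[a, b)``
    that fall inside the union of the indexed intervals, in O(log n) each.
    """

    def __init__(self, starts, ends) -> None:
        s, e = merge_union(starts, ends)
        self._s, self._e = s, e
        # cumulative covered bases up to the start of each union interval
        self._cum = np.concatenate([[0], np.cumsum(e - s)])

    def _covered_upto(self, pos: np.ndarray) -> np.ndarray:
        """Union bases in [-inf, pos)."""
        i = np.searchsorted(self._s, pos, side="right") - 1
        base = self._cum[np.maximum(i + 1, 0)]
        # subtract the part of interval i beyond pos, if pos falls inside it
        inside = i >= 0
        trim = np.zeros_like(pos)
        if np.any(inside):
            ii = i[inside]
            trim[inside] = np.maximum(self._e[ii] - np.maximum(self._s[ii], pos[inside]), 0)
        return base - trim

    def covered(self, starts, ends) -> np.ndarray:
        a = np.asarray(starts, dtype=np.int64)
        b = np.asarray(ends, dtype=np.int64)
        return self._covered_upto(b) - self._covered_upto(a)
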