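"""Sorted-interval helpers used throughout the package.

All intervals are 0-based half-open ``[start, end)``. A "track" is a
``(n, 2)`` integer array of merged (non-overlapping, sorted) intervals on one
chromosome. These helpers back the per-molecule hot loops (region merging,
annotation overlap, footprint geometry) and are verified against brute-force
bitmap oracles in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "overlaps_any",
    "overlap_lengths",
    "gap_distance",
    "as_track",
]


def as_track(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) to an ``(n, 2)`` int array."""
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2).astype(np.int64)
    return arr


def merge_intervals(intervals, *, merge_abutting: bool = True) -> np.ndarray:
    """Union of intervals; overlapping (and by default abutting) runs are merged.

    Returns a sorted ``(m, 2)`` array.
    """
    arr = as_track(intervals)
    if len(arr) == 0:
        return arr
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s < out[-1][1] or (merge_abutting and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def overlaps_any(starts, ends, track: np.ndarray) -> np.ndarray:
    """Vectorized: does each query ``[start, end)`` overlap >=1 bp of the track?

    ``track`` must be merged/sorted (see :func:`merge_intervals`).
    """
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    if len(track) == 0:
        return np.zeros(len(starts), dtype=bool)
    # candidate = first track interval whose end is > query start
    idx = np.searchsorted(track[:, 1], starts, side="right")
    hit = idx < len(track)
    out = np.zeros(len(starts), dtype=bool)
    out[hit] = track[idx[hit], 0] < ends[hit]
    return out


def overlap_lengths(starts, ends, track: np.ndarray) -> np.ndarray:
    """Total overlapped bp of each query interval with a merged track."""
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    out = np.zeros(len(starts), dtype=np.int64)
    if len(track) == 0:
        return out
    cum = np.concatenate([[0], np.cumsum(track[:, 1] - track[:, 0])])
    for i, (s, e) in enumerate(zip(starts, ends)):
        lo = np.searchsorted(track[:, 1], s, side="right")
        hi = np.searchsorted(track[:, 0], e, side="left")
        if lo >= hi:
            continue
        total = cum[hi] - cum[lo]
        total -= max(0, s - track[lo, 0])
        total -= max(0, track[hi - 1, 1] - e)
        out[i] = total
    return out


def gap_distance(start: int, end: int, track: np.ndarray) -> int | None:
    """Half-open gap between ``[start, end)`` and the nearest track interval.

    0 when they overlap or abut; ``None`` for an empty track.
    """
    if len(track) == 0:
        return None
    if overlaps_any([start], [end], track)[0]:
        return 0
    i = np.searchsorted(track[:, 0], end, side="left")
    best = None
    if i < len(track):
        best = int(track[i, 0] - end)
    if i > 0:
        d = int(start - track[i - 1, 1])
        best = d if best is None else min(best, d)
    return max(0, best)
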