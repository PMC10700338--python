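"""Basepair-interval arithmetic.

All coordinates are 0-based half-open ``[start, end)`` (BED convention);
1-based closed coordinates appear only at VCF boundaries.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort intervals and merge any that overlap or touch."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def clip_intervals(intervals: list[Interval], lo: int, hi: int) -> list[Interval]:
    out = []
    for s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if e > s:
            out.append((s, e))
    return out


def subtract_intervals(span: Interval, intervals: list[Interval]) -> list[Interval]:
    """Complement of ``intervals`` within ``span``."""
    out = []
    cur = span[0]
    for s, e in merge_intervals(clip_intervals(intervals, *span)):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if span[1] > cur:
        out.append((cur, span[1]))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_length(a: list[Interval], b: list[Interval]) -> int:
    a, b = merge_intervals(a), merge_intervals(b)
    i = j = 0
    tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            tot += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return tot


def jaccard(a: list[Interval], b: list[Interval]) -> float:
    inter = intersect_length(a, b)
    union = total_length(a) + total_length(b) - inter
    return inter / union if union else 1.0


def overlaps_any(starts, ends, intervals: list[Interval]) -> np.ndarray:
    """Boolean vector: does [starts[i], ends[i]) overlap any interval."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    hit = np.zeros(starts.shape, dtype=bool)
    for s, e in intervals:
        hit |= (starts < e) & (ends > s)
    return hit
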