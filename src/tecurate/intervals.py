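"""Interval arithmetic on 0-based half-open intervals."""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    """Number of positions covered by the union of ``intervals``."""
    return sum(e - s for s, e in merge(intervals))


def overlap_length(interval: Interval, others: Sequence[Interval]) -> int:
    """Bases of ``interval`` covered by the union of ``others``."""
    s, e = interval
    if e <= s:
        raise ValueError(f"empty or inverted interval ({s}, {e})")
    return sum(
        max(0, min(e, oe) - max(s, os_)) for os_, oe in merge(others)
    )


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> list[Interval]:
    """Intersect each interval with [lo, hi), dropping empty results."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out
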