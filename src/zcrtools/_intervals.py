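"""Half-open integer interval arithmetic on sorted, non-overlapping lists.

All functions take and return lists of ``(start, end)`` tuples with
``start < end``, sorted by start and pairwise disjoint. These are the small
set-algebra primitives (merge, subtract, intersect) the rest of the package
builds on; keeping them in one place keeps coordinate handling auditable.
"""

from __future__ import annotations

Interval = tuple[int, int]


def validate(intervals: list[Interval], *, bound: int | None = None) -> None:
    """Raise ValueError unless intervals are sorted, disjoint and in-bounds."""
    prev_end = None
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if start < 0:
            raise ValueError(f"negative coordinate in ({start}, {end})")
        if bound is not None and end > bound:
            raise ValueError(f"interval ({start}, {end}) exceeds bound {bound}")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"intervals overlap or are unsorted at ({start}, {end})")
        prev_end = end


def merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and union possibly-overlapping or adjacent intervals."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b; both inputs sorted and disjoint."""
    out: list[Interval] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set intersection of two sorted disjoint interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if start < end:
            out.append((start, end))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(end - start for start, end in intervals)


def complement(intervals: list[Interval], length: int) -> list[Interval]:
    """Gaps between intervals within [0, length)."""
    return subtract([(0, length)], merge(intervals))


def overlaps_any(intervals: list[Interval], others: list[Interval]) -> bool:
    """True if any base is shared between the two sorted lists."""
    i = j = 0
    while i < len(intervals) and j < len(others):
        if intervals[i][1] <= others[j][0]:
            i += 1
        elif others[j][1] <= intervals[i][0]:
            j += 1
        else:
            return True
    return False
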