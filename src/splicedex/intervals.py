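"""Closed-interval arithmetic on 1-based inclusive genomic coordinates.

All functions take and return lists of ``(start, end)`` tuples with
``start <= end``. Inputs need not be sorted; outputs are sorted and
non-overlapping.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or bookended (adjacent) intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le + 1:  # adjacency merges: [1,5]+[6,9] -> [1,9]
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two merged interval lists."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(lists: list[list[Interval]]) -> list[Interval]:
    if not lists:
        return []
    acc = merge(lists[0])
    for ivs in lists[1:]:
        acc = intersect(acc, ivs)
        if not acc:
            break
    return acc


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intervals of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


def complement(intervals: list[Interval], lo: int, hi: int) -> list[Interval]:
    """Complement of ``intervals`` within ``[lo, hi]``."""
    return subtract([(lo, hi)], intervals)


def overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def total_len(intervals: list[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)
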