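"""Small interval-set utilities (0-based half-open throughout).

These back the coverage arithmetic of the structural and landscape stages
and are property-tested against brute-force per-base counting.
"""

from __future__ import annotations

from typing import Iterable

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals; intervals separated by < ``gap`` uncovered bases
    (or touching/overlapping when ``gap`` is 0) are merged."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s - out[-1][1] < max(gap, 1):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement_intervals(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Complement of the union of ``intervals`` within [0, length)."""
    out: list[Interval] = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s, e = max(s, 0), min(e, length)
        if e <= s:
            continue
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval sets (each first merged)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap(a: Interval, b: Interval) -> int:
    """Length of the overlap of two single intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
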