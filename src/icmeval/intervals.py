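"""Half-open interval algebra on a per-patient clock.

Every time interval in this package is half-open, ``[start, end)``, in
floating-point seconds on a clock that starts at 0 for each recording.
Intervals are plain ``(start, end)`` tuples and interval *sets* are lists of
such tuples.  A set is *normalized* when its intervals are sorted, pairwise
disjoint and non-empty.  All operations below return normalized sets, so
overlap arithmetic (intersection lengths, set differences) is exact up to
float rounding — no sampling grid is involved.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[float, float]
IntervalSet = list[Interval]


def normalize(intervals: Iterable[Sequence[float]]) -> IntervalSet:
    """Sort, drop empty intervals, and merge overlapping or touching ones."""
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    out: IntervalSet = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total(intervals: Iterable[Sequence[float]]) -> float:
    """Total length of a normalized interval set."""
    return float(sum(e - s for s, e in intervals))


def union(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> IntervalSet:
    return normalize(list(a) + list(b))


def intersect(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> IntervalSet:
    """Intersection of two interval sets (two-pointer sweep)."""
    aa, bb = normalize(a), normalize(b)
    out: IntervalSet = []
    i = j = 0
    while i < len(aa) and j < len(bb):
        s = max(aa[i][0], bb[j][0])
        e = min(aa[i][1], bb[j][1])
        if e > s:
            out.append((s, e))
        if aa[i][1] <= bb[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> IntervalSet:
    """Set difference a \\ b."""
    aa, bb = normalize(a), normalize(b)
    out: IntervalSet = []
    j = 0
    for s, e in aa:
        cur = s
        while j < len(bb) and bb[j][1] <= cur:
            j += 1
        k = j
        while k < len(bb) and bb[k][0] < e:
            bs, be = bb[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Iterable[Sequence[float]], window: Sequence[float]) -> IntervalSet:
    """Restrict an interval set to a single window ``[lo, hi)``."""
    return intersect(intervals, [tuple(window)])


def overlap_length(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> float:
    return total(intersect(a, b))
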