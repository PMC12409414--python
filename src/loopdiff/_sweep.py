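"""Sweep-line primitives for interval/point joins in half-open coordinates.

Both joins run in O((n + m) log(n + m) + |output|). Inputs are plain tuples
(`(chrom, start, end, key)` / `(chrom, pos, key)`); callers adapt their domain
objects. Half-open semantics: an interval ending at ``p`` does not cover a
point or interval starting at ``p``, which fixes the event ordering below
(closes before opens before point queries at equal positions).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Hashable, Iterable, Sequence

Interval = tuple[str, int, int, Hashable]
Point = tuple[str, int, Hashable]

_CLOSE, _OPEN, _QUERY = 0, 1, 2


def point_in_interval_join(
    points: Sequence[Point], intervals: Sequence[Interval]
) -> list[tuple[Hashable, Hashable]]:
    """All (point_key, interval_key) pairs with ``pos in [start, end)``."""
    by_chrom_pts: dict[str, list[Point]] = defaultdict(list)
    by_chrom_ivs: dict[str, list[Interval]] = defaultdict(list)
    for p in points:
        by_chrom_pts[p[0]].append(p)
    for iv in intervals:
        if iv[1] >= iv[2]:
            raise ValueError(f"degenerate interval {iv}")
        by_chrom_ivs[iv[0]].append(iv)

    out: list[tuple[Hashable, Hashable]] = []
    for chrom in sorted(set(by_chrom_pts) & set(by_chrom_ivs)):
        events: list[tuple[int, int, Hashable]] = []
        for _, start, end, key in by_chrom_ivs[chrom]:
            events.append((start, _OPEN, key))
            events.append((end, _CLOSE, key))
        for _, pos, key in by_chrom_pts[chrom]:
            events.append((pos, _QUERY, key))
        events.sort(key=lambda e: (e[0], e[1]))
        active: dict[Hashable, None] = {}
        for _, kind, key in events:
            if kind == _OPEN:
                active[key] = None
            elif kind == _CLOSE:
                del active[key]
            else:
                out.extend((key, ikey) for ikey in active)
    return out


def interval_overlap_join(
    left: Sequence[Interval], right: Sequence[Interval]
) -> list[tuple[Hashable, Hashable]]:
    """All (left_key, right_key) pairs whose intervals overlap by >= 1 bp."""
    by_chrom: dict[str, tuple[list[Interval], list[Interval]]] = defaultdict(
        lambda: ([], [])
    )
    for iv in left:
        if iv[1] >= iv[2]:
            raise ValueError(f"degenerate interval {iv}")
        by_chrom[iv[0]][0].append(iv)
    for iv in right:
        if iv[1] >= iv[2]:
            raise ValueError(f"degenerate interval {iv}")
        by_chrom[iv[0]][1].append(iv)

    out: list[tuple[Hashable, Hashable]] = []
    for chrom in sorted(by_chrom):
        lefts, rights = by_chrom[chrom]
        events: list[tuple[int, int, int, Hashable]] = []
        for side, ivs in ((0, lefts), (1, rights)):
            for _, start, end, key in ivs:
                events.append((start, _OPEN, side, key))
                events.append((end, _CLOSE, side, key))
        events.sort(key=lambda e: (e[0], e[1]))
        active: tuple[dict, dict] = ({}, {})
        for _, kind, side, key in events:
            if kind == _CLOSE:
                del active[side][key]
                continue
            other = active[1 - side]
            if side == 0:
                out.extend((key, okey) for okey in other)
            else:
                out.extend((okey, key) for okey in other)
            active[side][key] = None
    return out


def overlapping_keys(
    query: Sequence[Interval], subject: Sequence[Interval]
) -> set:
    """Keys of ``query`` intervals overlapping >= 1 ``subject`` interval."""
    return {q for q, _ in interval_overlap_join(query, subject)}
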