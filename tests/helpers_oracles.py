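"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n·m) all-pairs scans, union-find
closures, exhaustive combinatorial sums — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

from loopdiff.core import ChromatinLoop, GenomicInterval, LoopSet, VariantRecord


def iv_overlap(a: GenomicInterval, b: GenomicInterval, slack_a: int = 0, slack_b: int = 0) -> bool:
    if a.chrom != b.chrom:
        return False
    a0, a1 = a.start - slack_a, a.end + slack_a
    b0, b1 = b.start - slack_b, b.end + slack_b
    return a0 < b1 and b0 < a1


def brute_classify(set_a: LoopSet, set_b: LoopSet, slack_bins: int = 0) -> dict[str, str]:
    """All-pairs loop classification; returns loop_id -> match class."""
    out: dict[str, str] = {}
    for me, other in ((set_a, set_b), (set_b, set_a)):
        for lp in me:
            both = one = False
            for oth in other:
                s = slack_bins * min(lp.resolution_bp, oth.resolution_bp)
                ll = iv_overlap(lp.anchor_left, oth.anchor_left, s, s)
                rr = iv_overlap(lp.anchor_right, oth.anchor_right, s, s)
                lr = iv_overlap(lp.anchor_left, oth.anchor_right, s, s)
                rl = iv_overlap(lp.anchor_right, oth.anchor_left, s, s)
                if ll and rr:
                    both = True
                if ll or rr or lr or rl:
                    one = True
            out[lp.loop_id] = (
                "shared_loop" if both else "shared_single_anchor" if one else "unique"
            )
    return out


def brute_point_hits(
    variants: Sequence[VariantRecord], contacts: Sequence[GenomicInterval]
) -> set[tuple[str, tuple]]:
    """(rsid, contact-coordinates) pairs with pos in [start, end), all pairs."""
    hits = set()
    for v in variants:
        for c in set(contacts):
            if c.chrom == v.chrom and c.start <= v.pos < c.end:
                hits.add((v.rsid, (c.chrom, c.start, c.end)))
    return hits


def brute_interval_pairs(
    left: Sequence[tuple[str, int, int, str]], right: Sequence[tuple[str, int, int, str]]
) -> set[tuple[str, str]]:
    """All (left_key, right_key) with >= 1 bp overlap, all pairs."""
    out = set()
    for lc, ls, le, lk in left:
        for rc, rs, re_, rk in right:
            if lc == rc and ls < re_ and rs < le:
                out.add((lk, rk))
    return out


def brute_cluster(
    positions: Sequence[tuple[str, int, str]], gap_bp: int, min_size: int
) -> list[tuple[str, ...]]:
    """Union-find closure over all pairs within gap_bp; size-filtered.

    ``positions`` are (chrom, pos, rsid); returns member tuples sorted by
    (chrom, first position), members position-sorted.
    """
    n = len(positions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if positions[i][0] == positions[j][0] and abs(positions[i][1] - positions[j][1]) <= gap_bp:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    kept = [g for g in groups.values() if len(g) >= min_size]
    kept.sort(key=lambda g: (positions[g[0]][0], min(positions[i][1] for i in g)))
    return [
        tuple(
            positions[i][2]
            for i in sorted(g, key=lambda i: (positions[i][1], positions[i][2]))
        )
        for g in kept
    ]


def exhaustive_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct combinatorial sum over the whole support."""
    total = comb(N, n)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return num / total


def exhaustive_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = comb(N, c1)

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, c1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def bh_stepup_by_hand(pvals: Sequence[float]) -> list[float]:
    """BH step-up computed literally from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
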