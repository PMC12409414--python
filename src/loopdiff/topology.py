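"""Cross-cell-type loop classification and contact-region extraction.

Two loop sets (eg precursor cells vs the differentiated cell type) are
compared loop-by-loop. A loop is ``shared_loop`` when some loop in the other
set matches at both anchors, ``shared_single_anchor`` when exactly one anchor
matches (one end keeps its contact, the other goes elsewhere), and ``unique``
otherwise — the differential loop locus (DLL) class. Anchor matching is
overlap-based: two anchors match when their intervals overlap by >= 1 bp after
each is widened by ``slack_bins`` bins of the smaller of the two call
resolutions; slack 0 means raw >= 1 bp overlap. Loop calls are never
re-scored here — classification is pure presence/absence set algebra on
called loops.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from scipy import stats

from ._sweep import interval_overlap_join, overlapping_keys
from .core import (
    ChromatinLoop,
    DLLRecord,
    GenomicInterval,
    LoopSet,
    ValidationError,
)


def _check_canonical(loop_set: LoopSet) -> None:
    for lp in loop_set:
        if lp.anchor_left.start > lp.anchor_right.start:
            raise ValidationError(
                f"loop set {loop_set.cell_label!r} not canonicalized at {lp.loop_id}"
            )


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _anchor_pairs(
    set_a: LoopSet, set_b: LoopSet, slack_bins: int
) -> dict[tuple[str, str], set[tuple[int, int]]]:
    """Map (a_id, b_id) -> set of (a_side, b_side) anchor matches (0=left, 1=right).

    Anchors are widened by ``slack_bins * min(res_a, res_b)`` in total (each of
    the pair contributes half via widening both); computed as a sweep join of
    widened A anchors against raw B anchors per resolution pair, collapsed to
    widening by the full slack on the A side only — equivalent for overlap
    tests since overlap(widen(a, s), widen(b, s)) == overlap(widen(a, 2s), b).
    """
    by_res_b: dict[int, list] = defaultdict(list)
    for lp in set_b:
        for side, anchor in enumerate(lp.anchors):
            by_res_b[lp.resolution_bp].append(
                (anchor.chrom, anchor.start, anchor.end, (lp.loop_id, side))
            )

    pairs: dict[tuple[str, str], set[tuple[int, int]]] = defaultdict(set)
    for res_b, b_ivs in by_res_b.items():
        a_ivs = []
        for lp in set_a:
            slack = slack_bins * min(lp.resolution_bp, res_b)
            for side, anchor in enumerate(lp.anchors):
                w = anchor.widened(2 * slack)
                a_ivs.append((w.chrom, w.start, w.end, (lp.loop_id, side)))
        for (a_id, a_side), (b_id, b_side) in interval_overlap_join(a_ivs, b_ivs):
            pairs[(a_id, b_id)].add((a_side, b_side))
    return pairs


def _classify_one_direction(
    set_a: LoopSet,
    set_b: LoopSet,
    pairs: dict[tuple[str, str], set[tuple[int, int]]],
) -> list[DLLRecord]:
    b_by_id = {lp.loop_id: lp for lp in set_b}
    a_matches: dict[str, dict[str, set[tuple[int, int]]]] = defaultdict(dict)
    for (a_id, b_id), sides in pairs.items():
        a_matches[a_id][b_id] = sides

    records = []
    for lp in set_a:
        matches = a_matches.get(lp.loop_id, {})
        shared_partners = [
            b_id
            for b_id, sides in matches.items()
            if (0, 0) in sides and (1, 1) in sides
        ]
        if shared_partners:
            # deterministic partner: maximal summed anchor overlap, then
            # smallest (chrom, start, loop_id)
            def sort_key(b_id: str):
                b = b_by_id[b_id]
                total = _overlap_bp(lp.anchor_left, b.anchor_left) + _overlap_bp(
                    lp.anchor_right, b.anchor_right
                )
                return (-total, b.chrom, b.anchor_left.start, b_id)

            best = min(shared_partners, key=sort_key)
            records.append(
                DLLRecord(lp.loop_id, set_a.cell_label, "shared_loop", best)
            )
        elif matches:
            records.append(
                DLLRecord(lp.loop_id, set_a.cell_label, "shared_single_anchor")
            )
        else:
            records.append(DLLRecord(lp.loop_id, set_a.cell_label, "unique"))
    return records


def match_loops(
    set_a: LoopSet, set_b: LoopSet, slack_bins: int = 0
) -> tuple[list[DLLRecord], list[DLLRecord]]:
    """Classify every loop of each set against the other set.

    Returns one DLLRecord list per set, in input loop order. Classification is
    symmetric: the number of ``shared_loop`` records is equal in both
    directions.
    """
    if slack_bins < 0:
        raise ValidationError("slack_bins must be >= 0")
    _check_canonical(set_a)
    _check_canonical(set_b)
    pairs_ab = _anchor_pairs(set_a, set_b, slack_bins)
    pairs_ba = {
        (b_id, a_id): {(bs, as_) for (as_, bs) in sides}
        for (a_id, b_id), sides in pairs_ab.items()
    }
    return (
        _classify_one_direction(set_a, set_b, pairs_ab),
        _classify_one_direction(set_b, set_a, pairs_ba),
    )


def dll_class_counts(records: Iterable[DLLRecord]) -> dict[str, int]:
    counts = {"shared_loop": 0, "shared_single_anchor": 0, "unique": 0}
    for rec in records:
        counts[rec.match_class] += 1
    return counts


def contact_regions(loop_set: LoopSet) -> list[GenomicInterval]:
    """Unique loop anchors (exact-coordinate uniqueness), sorted."""
    return sorted({anchor for lp in loop_set for anchor in lp.anchors})


def unique_loops(loop_set: LoopSet, records: Sequence[DLLRecord]) -> LoopSet:
    """Subset of the loop set classified ``unique`` (the DLLs)."""
    uniq = {r.loop_id for r in records if r.match_class == "unique"}
    return LoopSet(
        cell_label=loop_set.cell_label,
        loops=tuple(lp for lp in loop_set if lp.loop_id in uniq),
    )


def contact_annotation_fraction(
    contacts: Sequence[GenomicInterval], annotation: Sequence[GenomicInterval]
) -> float:
    """Fraction of contact regions overlapping >= 1 annotation interval.

    Used eg to ask what share of loop contacts fall in enhancer-state
    chromatin from an external annotation track.
    """
    if not contacts:
        return 0.0
    query = [(c.chrom, c.start, c.end, i) for i, c in enumerate(contacts)]
    subject = [(a.chrom, a.start, a.end, j) for j, a in enumerate(annotation)]
    # dedup identical contact coordinates before counting
    n_unique = len({(c.chrom, c.start, c.end) for c in contacts})
    hit_coords = {
        (contacts[i].chrom, contacts[i].start, contacts[i].end)
        for i in overlapping_keys(query, subject)
    }
    return len(hit_coords) / n_unique


def region_loop_count_test(
    count_a: int, count_b: int, method: str = "binomial"
) -> float:
    """Two-sided p-value for an imbalance in regional loop counts.

    Under the null, each of the ``count_a + count_b`` loops in a region is
    equally likely to come from either cell type. Default is the exact
    binomial test at p = 0.5, doubling the smaller tail and capping at 1;
    ``method="chi2"`` gives the 1-df goodness-of-fit alternative.
    """
    if count_a < 0 or count_b < 0:
        raise ValidationError("negative loop count")
    n = count_a + count_b
    if n == 0:
        raise ValidationError("region_loop_count_test undefined for (0, 0)")
    if method == "binomial":
        k = min(count_a, count_b)
        p = 2.0 * float(stats.binom.cdf(k, n, 0.5))
        return min(1.0, p)
    if method == "chi2":
        return float(stats.chisquare([count_a, count_b]).pvalue)
    raise ValidationError(f"unknown method {method!r}")


def merge_resolutions(loop_sets: Sequence[LoopSet], cell_label: str) -> LoopSet:
    """Combine per-resolution call sets into one set of unique loops.

    A loop detected at several scales (identical anchor coordinates) is kept
    once, as the record with the smallest call resolution — the most precise
    anchors.
    """
    best: dict[tuple, ChromatinLoop] = {}
    for ls in loop_sets:
        for lp in ls:
            key = (
                lp.anchor_left.chrom,
                lp.anchor_left.start,
                lp.anchor_left.end,
                lp.anchor_right.start,
                lp.anchor_right.end,
            )
            if key not in best or lp.resolution_bp < best[key].resolution_bp:
                best[key] = lp
    return LoopSet(cell_label=cell_label, loops=tuple(best[k] for k in sorted(best)))
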