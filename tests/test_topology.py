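"""Loop classification, contact regions and the regional count test."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_intervals, random_loop_set
from helpers_oracles import brute_classify, brute_interval_pairs

from loopdiff.core import ChromatinLoop, GenomicInterval, LoopSet, ValidationError
from loopdiff.topology import (
    contact_annotation_fraction,
    contact_regions,
    dll_class_counts,
    match_loops,
    merge_resolutions,
    region_loop_count_test,
)


def _loop(lid, chrom, s1, e1, s2, e2, res=1000):
    return ChromatinLoop(
        loop_id=lid,
        anchor_left=GenomicInterval(chrom, s1, e1),
        anchor_right=GenomicInterval(chrom, s2, e2),
        resolution_bp=res,
    )


class TestMatchLoops:
    def test_constructed_shared_and_single_anchor(self):
        set_a = LoopSet("A", (
            _loop("L1", "chr1", 0, 1000, 5000, 6000),
            _loop("L2", "chr1", 0, 1000, 9000, 10000),
        ))
        set_b = LoopSet("B", (_loop("M1", "chr1", 0, 1000, 5000, 6000),))
        dll_a, dll_b = match_loops(set_a, set_b, slack_bins=0)
        by_id = {r.loop_id: r for r in dll_a + dll_b}
        assert by_id["L1"].match_class == "shared_loop"
        assert by_id["L1"].matched_loop_id == "M1"
        assert by_id["L2"].match_class == "shared_single_anchor"
        assert by_id["M1"].match_class == "shared_loop"

    def test_identical_sets_have_no_unique_loops(self):
        rng = np.random.default_rng(3)
        set_a = random_loop_set(rng, "A", 30)
        set_b = LoopSet("B", tuple(
            ChromatinLoop(f"B{i}", lp.anchor_left, lp.anchor_right, lp.resolution_bp)
            for i, lp in enumerate(set_a)
        ))
        dll_a, dll_b = match_loops(set_a, set_b)
        assert dll_class_counts(dll_a)["unique"] == 0
        assert dll_class_counts(dll_b)["unique"] == 0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("slack", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed, slack):
        rng = np.random.default_rng([seed, slack])
        set_a = random_loop_set(rng, "A", 50)
        set_b = random_loop_set(rng, "B", 50)
        dll_a, dll_b = match_loops(set_a, set_b, slack_bins=slack)
        expected = brute_classify(set_a, set_b, slack_bins=slack)
        got = {r.loop_id: r.match_class for r in dll_a + dll_b}
        assert got == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_counts_symmetric_and_partition(self, seed):
        rng = np.random.default_rng(seed)
        set_a = random_loop_set(rng, "A", 40)
        set_b = random_loop_set(rng, "B", 25)
        dll_a, dll_b = match_loops(set_a, set_b)
        ca, cb = dll_class_counts(dll_a), dll_class_counts(dll_b)
        assert ca["shared_loop"] == cb["shared_loop"]
        assert sum(ca.values()) == len(set_a)
        assert sum(cb.values()) == len(set_b)

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_count_monotone_in_slack(self, seed):
        rng = np.random.default_rng(seed)
        set_a = random_loop_set(rng, "A", 40)
        set_b = random_loop_set(rng, "B", 40)
        counts = [
            dll_class_counts(match_loops(set_a, set_b, slack_bins=s)[0])["shared_loop"]
            for s in (0, 1, 2, 4)
        ]
        assert counts == sorted(counts)

    def test_uncanonical_input_rejected(self):
        with pytest.raises(ValidationError):
            ChromatinLoop(
                "X", GenomicInterval("chr1", 5000, 6000), GenomicInterval("chr1", 0, 1000), 1000
            )


class TestContactRegions:
    def test_shared_anchor_collapses(self):
        s = LoopSet("A", (
            _loop("L1", "chr1", 0, 1000, 5000, 6000),
            _loop("L2", "chr1", 0, 1000, 9000, 10000),
        ))
        assert len(contact_regions(s)) == 3

    def test_empty_set(self):
        assert contact_regions(LoopSet("A", ())) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_unique_count_matches_set_of_tuples(self, seed):
        rng = np.random.default_rng(seed)
        s = random_loop_set(rng, "A", 100)
        expected = {(a.chrom, a.start, a.end) for lp in s for a in lp.anchors}
        got = contact_regions(s)
        assert len(got) == len(expected)
        assert got == sorted(got)
        assert len(got) <= 2 * len(s)


class TestAnnotationFraction:
    def test_full_and_zero_overlap(self):
        contacts = [GenomicInterval("chr1", 0, 1000)]
        assert contact_annotation_fraction(contacts, [GenomicInterval("chr1", 500, 600)]) == 1.0
        assert contact_annotation_fraction(contacts, [GenomicInterval("chr1", 5000, 5600)]) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_fraction(self, seed):
        rng = np.random.default_rng(seed)
        contacts = random_intervals(rng, 200)
        annot = random_intervals(rng, 200)
        uniq = {(c.chrom, c.start, c.end) for c in contacts}
        hit = {
            c for c in uniq
            if any(a.chrom == c[0] and a.start < c[2] and c[1] < a.end for a in annot)
        }
        assert contact_annotation_fraction(contacts, annot) == pytest.approx(len(hit) / len(uniq))


class TestRegionLoopCountTest:
    @pytest.mark.parametrize(
        "a,b,expected", [(22, 7, 0.00813), (6, 3, 0.5078)],
    )
    def test_doubled_tail_examples(self, a, b, expected):
        assert region_loop_count_test(a, b) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_balanced_counts_give_one(self, k):
        assert region_loop_count_test(k, k) == 1.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            region_loop_count_test(0, 0)

    def test_chi2_alternative_available(self):
        p = region_loop_count_test(22, 7, method="chi2")
        assert 0 < p < 0.01


class TestMergeResolutions:
    def test_duplicate_kept_at_smallest_resolution(self):
        fine = LoopSet("A1k", (_loop("f", "chr1", 0, 1000, 5000, 6000, res=1000),))
        coarse = LoopSet("A4k", (
            _loop("c", "chr1", 0, 1000, 5000, 6000, res=4000),
            _loop("c2", "chr1", 8000, 12000, 16000, 20000, res=4000),
        ))
        merged = merge_resolutions([fine, coarse], "A")
        assert len(merged) == 2
        by_coord = {(lp.anchor_left.start, lp.anchor_right.start): lp for lp in merged}
        assert by_coord[(0, 5000)].resolution_bp == 1000
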