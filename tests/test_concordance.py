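"""SNP clustering and SNP/DEG/contact concordance windows."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_intervals, random_variants
from helpers_oracles import brute_cluster, brute_interval_pairs

from loopdiff.core import (
    ConfigError,
    GeneRecord,
    GenomicInterval,
    SNPCluster,
    VariantRecord,
)
from loopdiff.concordance import (
    cluster_variants,
    genes_near_contacts,
    overlap_clusters_degs,
    variants_near_genes,
)


def _vars_at(positions, chrom="chr1"):
    return [
        VariantRecord(f"rs{i:04d}", chrom, p, "bone", True, 1e-8, 1.0)
        for i, p in enumerate(positions)
    ]


class TestClusterVariants:
    def test_chaining_and_size_filter(self):
        clusters = cluster_variants(_vars_at([100, 4000, 8000, 20000]), 5000, 10)
        assert clusters == []
        # same chains retained when the size filter allows them
        chains = cluster_variants(_vars_at([100, 4000, 8000, 20000]), 5000, 1)
        assert [(c.first_pos, c.last_pos, len(c.members)) for c in chains] == [
            (100, 8000, 3),
            (20000, 20000, 1),
        ]

    def test_ten_evenly_spaced_variants_span(self):
        clusters = cluster_variants(_vars_at(list(range(0, 10_000, 1000))), 5000, 10)
        assert len(clusters) == 1
        assert clusters[0].span_bp == 9000
        assert len(clusters[0].members) == 10

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        variants = random_variants(rng, 1000, chrom_len=2_000_000)
        clusters = cluster_variants(variants, gap_bp=5000, min_size=3)
        got = [c.members for c in clusters]
        expected = brute_cluster(
            [(v.chrom, v.pos, v.rsid) for v in variants], gap_bp=5000, min_size=3
        )
        assert got == expected

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(5)
        variants = random_variants(rng, 300, chrom_len=300_000)
        clusters = cluster_variants(variants, 5000, 5)
        reversed_clusters = cluster_variants(variants[::-1], 5000, 5)
        assert [c.members for c in clusters] == [c.members for c in reversed_clusters]
        by_rsid = {v.rsid: v for v in variants}
        for c in clusters:
            again = cluster_variants([by_rsid[r] for r in c.members], 5000, len(c.members))
            assert len(again) == 1 and again[0].members == c.members

    def test_negative_config_rejected(self):
        with pytest.raises(ConfigError):
            cluster_variants([], gap_bp=-1)


def _cluster(cid, chrom, first, last, n=10):
    return SNPCluster(cid, chrom, tuple(f"{cid}_m{i}" for i in range(n)), first, last)


def _gene(gid, chrom, start, end, strand="+"):
    return GeneRecord(gid, chrom, start, end, strand)


class TestOverlapClustersDegs:
    def test_containment_and_disjoint(self):
        clusters = [_cluster("c1", "chr1", 11_000, 15_000), _cluster("c2", "chr1", 0, 100)]
        genes = [_gene("g1", "chr1", 10_000, 20_000), _gene("g2", "chr1", 200, 300)]
        n_cl, n_deg, pairs = overlap_clusters_degs(clusters, genes)
        assert pairs == [("c1", "g1")]
        assert (n_cl, n_deg) == (1, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        clusters = [
            _cluster(f"c{i}", iv.chrom, iv.start, iv.end - 1)
            for i, iv in enumerate(random_intervals(rng, 100, chrom_len=500_000))
        ]
        genes = [
            _gene(f"g{i}", iv.chrom, iv.start, iv.end)
            for i, iv in enumerate(random_intervals(rng, 50, chrom_len=500_000))
        ]
        _, _, pairs = overlap_clusters_degs(clusters, genes)
        left = [(c.chrom, c.interval.start, c.interval.end, c.cluster_id) for c in clusters]
        right = [(g.chrom, g.start, g.end, g.gene_id) for g in genes]
        assert set(pairs) == brute_interval_pairs(left, right)


class TestVariantsNearGenes:
    def test_window_arithmetic_with_floor(self):
        gene = _gene("g1", "chr1", 10_000, 20_000)
        inside = _vars_at([65_000])  # [max(0,-40000), 70000) at w=50k
        at_edge = _vars_at([70_000])
        got_in = variants_near_genes(inside, [gene], windows_bp=[50_000])[0]
        got_edge = variants_near_genes(at_edge, [gene], windows_bp=[50_000])[0]
        assert (got_in.unique_left_count, got_in.unique_right_count) == (1, 1)
        assert (got_edge.unique_left_count, got_edge.unique_right_count) == (0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_at_every_window(self, seed):
        rng = np.random.default_rng(seed)
        variants = random_variants(rng, 300, chrom_len=2_000_000)
        genes = [
            _gene(f"g{i}", iv.chrom, iv.start, iv.end)
            for i, iv in enumerate(random_intervals(rng, 40, chrom_len=2_000_000))
        ]
        for s in variants_near_genes(variants, genes):
            w = s.window_bp
            hits = {
                (v.rsid, g.gene_id)
                for v in variants
                for g in genes
                if v.chrom == g.chrom and max(0, g.start - w) <= v.pos < g.end + w
            }
            assert s.unique_left_count == len({r for r, _ in hits})
            assert s.unique_right_count == len({g for _, g in hits})

    def test_counts_monotone_in_window(self):
        rng = np.random.default_rng(9)
        variants = random_variants(rng, 400, chrom_len=3_000_000)
        genes = [
            _gene(f"g{i}", iv.chrom, iv.start, iv.end)
            for i, iv in enumerate(random_intervals(rng, 30, chrom_len=3_000_000))
        ]
        summaries = variants_near_genes(variants, genes)
        lefts = [s.unique_left_count for s in summaries]
        rights = [s.unique_right_count for s in summaries]
        assert lefts == sorted(lefts) and rights == sorted(rights)


class TestGenesNearContacts:
    def test_window_brings_gene_in(self):
        gene = _gene("g1", "chr1", 10_000, 20_000)
        contact = GenomicInterval("chr1", 25_000, 26_000)
        out = genes_near_contacts([gene], [contact], windows_bp=[0, 50_000])
        assert out[0]["deg_in_window"] == 0
        assert out[1]["deg_in_window"] == 1
        assert all(o["deg_total"] == 1 for o in out)

    def test_empty_contacts(self):
        genes = [_gene("g1", "chr1", 0, 1000)]
        assert all(
            o["deg_in_window"] == 0 for o in genes_near_contacts(genes, [])
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        genes = [
            _gene(f"g{i}", iv.chrom, iv.start, iv.end)
            for i, iv in enumerate(random_intervals(rng, 60, chrom_len=2_000_000))
        ]
        contacts = random_intervals(rng, 40, chrom_len=2_000_000)
        out = genes_near_contacts(genes, contacts)
        xs = []
        for o in out:
            w = o["window_bp"]
            expected = {
                g.gene_id
                for g in genes
                for c in contacts
                if g.chrom == c.chrom and g.start < c.end + w and max(0, c.start - w) < g.end
            }
            assert o["deg_in_window"] == len(expected)
            xs.append(o["deg_in_window"])
        assert xs == sorted(xs)
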