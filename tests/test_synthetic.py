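"""Planted ground truth, determinism and capacity errors of the generator."""

from __future__ import annotations

from collections import Counter

import pytest

from conftest import SMALL
from helpers_oracles import brute_classify, brute_point_hits

from loopdiff.core import GenerationError
from loopdiff.synthetic import (
    SyntheticConfig,
    TruthManifest,
    generate_dataset,
    generate_genome,
    generate_loop_sets,
    largest_remainder,
)
from loopdiff.topology import contact_regions


class TestConfigAndGenome:
    def test_genome_echoes_config(self):
        cfg = SyntheticConfig(n_chromosomes=2, chrom_length_bp=1_000_000)
        genome = generate_genome(cfg)
        assert genome == {"chr1": 1_000_000, "chr2": 1_000_000}

    def test_zero_chromosomes_is_vacuous(self):
        assert generate_genome(SyntheticConfig(n_chromosomes=0)) == {}

    def test_invalid_fractions_rejected(self):
        from loopdiff.core import ConfigError

        with pytest.raises(ConfigError):
            SyntheticConfig(frac_shared_loops=0.7, frac_shared_single_anchor=0.5)
        with pytest.raises(ConfigError):
            SyntheticConfig(anchor_resolutions_bp=(1000, 1000))

    @pytest.mark.parametrize(
        "total,fracs,expected",
        [
            (10, [0.5, 0.0, 0.5], [5, 0, 5]),
            (10, [0.3, 0.33, 0.37], [3, 3, 4]),
            (7, [0.5, 0.5], [4, 3]),  # tie goes to the earlier class
            (0, [0.2, 0.8], [0, 0]),
        ],
    )
    def test_largest_remainder_sums_exactly(self, total, fracs, expected):
        got = largest_remainder(total, fracs)
        assert got == expected and sum(got) == total


class TestLoopPlanting:
    def test_exact_class_fractions(self):
        cfg = SyntheticConfig(
            seed=3, n_loops_per_cell=10, frac_shared_loops=0.5,
            frac_shared_single_anchor=0.0,
        )
        set_a, set_b, manifest = generate_loop_sets(cfg, generate_genome(cfg))
        counts = Counter(manifest.loop_class_by_id.values())
        assert counts == {"shared": 10, "unique_A": 5, "unique_B": 5}
        assert len(set_a) == len(set_b) == 10

    def test_all_shared_means_no_unique(self):
        from loopdiff.topology import dll_class_counts, match_loops

        cfg = SyntheticConfig(seed=3, n_loops_per_cell=10, frac_shared_loops=1.0,
                              frac_shared_single_anchor=0.0)
        set_a, set_b, _ = generate_loop_sets(cfg, generate_genome(cfg))
        dll_a, dll_b = match_loops(set_a, set_b)
        assert dll_class_counts(dll_a)["unique"] == 0
        assert dll_class_counts(dll_b)["unique"] == 0

    def test_single_anchor_class_verified_by_all_pairs(self):
        cfg = SyntheticConfig(seed=5, n_loops_per_cell=10, frac_shared_loops=0.0,
                              frac_shared_single_anchor=0.3)
        set_a, set_b, manifest = generate_loop_sets(cfg, generate_genome(cfg))
        oracle = brute_classify(set_a, set_b)
        planted_single_a = [
            i for i in manifest.loop_class_by_id
            if i.startswith("A") and manifest.loop_class_by_id[i] == "single_anchor"
        ]
        assert len(planted_single_a) == 3
        assert all(oracle[i] == "shared_single_anchor" for i in planted_single_a)

    def test_impossible_layout_raises_generation_error(self):
        cfg = SyntheticConfig(n_chromosomes=1, chrom_length_bp=300_000,
                              n_loops_per_cell=500, proxy_window_bp=10_000)
        with pytest.raises(GenerationError):
            generate_dataset(cfg)


class TestDatasetTruth:
    def test_truth_maps_cover_every_entity_once(self, small_dataset):
        ds = small_dataset
        loop_ids = {lp.loop_id for lp in ds.loop_set_a} | {lp.loop_id for lp in ds.loop_set_b}
        assert set(ds.manifest.loop_class_by_id) == loop_ids
        assert set(ds.manifest.snp_in_contact_by_id) == {v.rsid for v in ds.variants}

    def test_in_contact_truth_matches_exhaustive_check(self, small_dataset):
        ds = small_dataset
        for cell, loop_set in (("A", ds.loop_set_a), ("B", ds.loop_set_b)):
            contacts = contact_regions(loop_set)
            expected_in = {r for r, _ in brute_point_hits(ds.variants, contacts)}
            truth_in = {
                r for r, flags in ds.manifest.snp_in_contact_by_id.items() if flags[cell]
            }
            assert truth_in == expected_in

    def test_planted_deg_bodies_cover_their_clusters(self, small_dataset):
        ds = small_dataset
        genes = {g.gene_id: g for g in ds.genes}
        pos = {v.rsid: v.pos for v in ds.variants}
        members = ds.manifest.expected_cluster_memberships
        for cluster_id, gene_ids in ds.manifest.planted_deg_overlaps.items():
            idx = int(cluster_id.split("_")[1])
            first = min(pos[r] for r in members[idx])
            last = max(pos[r] for r in members[idx])
            for gid in gene_ids:
                g = genes[gid]
                assert g.start <= first and g.end > last

    def test_deg_fraction_planted_exactly(self, small_dataset):
        ds = small_dataset
        expected = largest_remainder(
            ds.config.n_genes, [ds.config.frac_deg, 1 - ds.config.frac_deg]
        )[0]
        assert len(ds.degs) == expected
        assert all(d.p_adj < 0.05 and d.log_fc != 0 for d in ds.degs)

    def test_planted_terms_draw_mostly_from_foreground(self, small_dataset):
        ds = small_dataset
        fg = set(ds.manifest.term_foreground_gene_ids)
        for term_id in ds.manifest.enriched_term_ids:
            members = ds.terms[term_id]
            assert sum(1 for m in members if m in fg) / len(members) >= 0.8


class TestDeterminism:
    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=11, **SMALL)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        paths1 = generate_dataset(cfg).write(out1)
        paths2 = generate_dataset(cfg).write(out2)
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(seed=1, **SMALL))
        b = generate_dataset(SyntheticConfig(seed=2, **SMALL))
        assert a.variants != b.variants

    def test_manifest_round_trips(self, small_dataset, tmp_path):
        path = tmp_path / "m.json"
        small_dataset.manifest.write(path)
        assert TruthManifest.read(path) == small_dataset.manifest
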