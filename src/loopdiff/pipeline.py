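"""End-to-end orchestration: one config in, one JSON report out.

Stages run in dependency order: loops → DLL classification → contact regions
→ SNP-to-contact mapping (study + control trait) → positional clustering →
DEG concordance windows → loop-anchored term enrichment. Inputs either come
from files named in the config or are generated by the synthetic module under
the config's seed; every stage's counts land in a schema-versioned report
that is byte-identical across runs with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import concordance as cc
from . import enrichment as en
from . import io as ldio
from . import snpmap as sm
from . import topology as tp
from .core import ConfigError, GeneRecord, LoopdiffError
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every input path and threshold of one pipeline run.

    Either ``synthetic`` is set (inputs are generated) or the input paths
    are. All printed thresholds of the analysis live here: the 5000 bp
    cluster gap, the 10-SNP minimum cluster size, r² > 0.6, p < 1e-5, the
    {0, 50, 200, 1000 kb} concordance windows, the ±1 kb promoter flank and
    the 0.05 significance level.
    """

    outdir: str = "loopdiff_out"
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    # input paths (ignored when synthetic is set)
    loops_a: Optional[str] = None
    loops_b: Optional[str] = None
    resolution_a_bp: int = 1000
    resolution_b_bp: int = 1000
    variants: Optional[str] = None
    genes: Optional[str] = None
    deg: Optional[str] = None
    terms_gmt: Optional[str] = None
    annotation_bed: Optional[str] = None
    # thresholds
    trait: str = "bone"
    control_trait: str = "control"
    assoc_p_threshold: float = 1e-5
    ld_r2_threshold: float = 0.6
    gap_bp: int = 5000
    min_cluster_size: int = 10
    windows_bp: tuple[int, ...] = cc.DEFAULT_WINDOWS_BP
    promoter_flank_bp: int = 1000
    slack_bins: int = 0
    alpha: float = 0.05
    region_test: str = "binomial"

    def __post_init__(self) -> None:
        for name in ("gap_bp", "min_cluster_size", "promoter_flank_bp", "slack_bins"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0,1)")
        if list(self.windows_bp) != sorted(self.windows_bp):
            raise ConfigError("windows_bp must be sorted ascending")
        if self.synthetic is None:
            required = ("loops_a", "loops_b", "variants", "genes", "deg", "terms_gmt")
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise ConfigError(
                    f"config needs either 'synthetic' or input paths; missing {missing}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(
            **{k: tuple(v) if k == "windows_bp" else v for k, v in raw.items()},
            synthetic=SyntheticConfig(**syn) if syn is not None else None,
        )
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        doc = asdict(self)
        doc.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed != config.seed:
            syn = SyntheticConfig(**{**asdict(syn), "seed": config.seed})
        ds = generate_dataset(syn)
        ds.write(outdir / "data")
        annotation = None
        return ds.loop_set_a, ds.loop_set_b, ds.variants, ds.genes, ds.degs, ds.terms, annotation
    set_a = ldio.read_loops(config.loops_a, config.resolution_a_bp, cell_label="A")
    set_b = ldio.read_loops(config.loops_b, config.resolution_b_bp, cell_label="B")
    variants = ldio.read_variant_table(config.variants)
    genes = ldio.read_gene_table(config.genes)
    degs = ldio.read_deg_table(config.deg)
    terms = ldio.read_gmt(config.terms_gmt)
    annotation = (
        ldio.read_bed(config.annotation_bed) if config.annotation_bed else None
    )
    return set_a, set_b, variants, genes, degs, terms, annotation


def _write_dll(records, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "loop_id": r.loop_id,
                "cell_label": r.cell_label,
                "match_class": r.match_class,
                "matched_loop_id": r.matched_loop_id or "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d config=%s", config.seed, config.config_hash())

    set_a, set_b, variants, genes, degs, terms, annotation = _load_inputs(config, outdir)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "loops": {
            "count_a": len(set_a),
            "count_b": len(set_b),
            "resolutions_a": sorted(set_a.resolutions_present),
            "resolutions_b": sorted(set_b.resolutions_present),
        },
    }

    # --- DLL classification -------------------------------------------------
    dll_a, dll_b = tp.match_loops(set_a, set_b, slack_bins=config.slack_bins)
    _write_dll(dll_a, outdir / "dll_A.tsv")
    _write_dll(dll_b, outdir / "dll_B.tsv")
    report["dll"] = {
        "class_counts_a": tp.dll_class_counts(dll_a),
        "class_counts_b": tp.dll_class_counts(dll_b),
        "regional_count_p": (
            tp.region_loop_count_test(len(set_a), len(set_b), config.region_test)
            if len(set_a) + len(set_b) > 0
            else None
        ),
    }

    # --- contact regions ----------------------------------------------------
    contacts_a = tp.contact_regions(set_a)
    contacts_b = tp.contact_regions(set_b)
    dll_set_a = tp.unique_loops(set_a, dll_a)
    dll_contacts_a = tp.contact_regions(dll_set_a)
    ldio.write_bed(contacts_a, outdir / "contacts_A.bed")
    ldio.write_bed(contacts_b, outdir / "contacts_B.bed")
    ldio.write_bed(dll_contacts_a, outdir / "dll_contacts_A.bed")
    report["contacts"] = {
        "unique_contacts_a": len(contacts_a),
        "unique_contacts_b": len(contacts_b),
        "dll_unique_contacts_a": len(dll_contacts_a),
    }
    if annotation is not None:
        report["contacts"]["annotation_fraction_a"] = tp.contact_annotation_fraction(
            contacts_a, annotation
        )

    # --- candidate selection and contact mapping ----------------------------
    selection = sm.CandidateSelection(
        assoc_p_threshold=config.assoc_p_threshold,
        ld_r2_threshold=config.ld_r2_threshold,
    )
    trait_vars = [v for v in variants if v.trait == config.trait]
    ctrl_vars = [v for v in variants if v.trait == config.control_trait]
    candidates, selection = sm.select_candidates(trait_vars, selection)
    ctrl_candidates, _ = sm.select_candidates(ctrl_vars, sm.CandidateSelection(
        assoc_p_threshold=config.assoc_p_threshold,
        ld_r2_threshold=config.ld_r2_threshold,
    ))

    hits, n_snps, n_contacts = sm.map_variants_to_contacts(candidates, contacts_a, "A")
    dll_hits, n_dll_snps, n_dll_contacts = sm.map_variants_to_contacts(
        candidates, dll_contacts_a, "A"
    )
    ctrl_hits, n_ctrl_snps, _ = sm.map_variants_to_contacts(ctrl_candidates, contacts_a, "A")
    pd.DataFrame(
        [
            {"rsid": h.rsid, "chrom": h.contact.chrom, "start": h.contact.start,
             "end": h.contact.end, "cell_label": h.cell_label}
            for h in hits
        ]
    ).to_csv(outdir / "contact_hits.tsv", sep="\t", index=False)

    snp_report = {
        "sentinel_count": selection.sentinel_count,
        "candidate_count": selection.candidate_count,
        "unique_snps_in_contacts": n_snps,
        "unique_contacts_with_snp": n_contacts,
        "unique_snps_in_dll_contacts": n_dll_snps,
        "unique_dll_contacts_with_snp": n_dll_contacts,
        "control_candidate_count": len(ctrl_candidates),
        "control_unique_snps_in_contacts": n_ctrl_snps,
    }
    if selection.candidate_count > 0:
        pct, pct_round = sm.fraction_in_contacts(n_snps, selection.candidate_count)
        snp_report["fraction_in_contacts_pct"] = pct
        snp_report["fraction_in_contacts_pct_rounded"] = pct_round
    if selection.candidate_count > 0 and len(ctrl_candidates) > 0:
        enr = sm.trait_enrichment_test(
            n_snps, selection.candidate_count, n_ctrl_snps, len(ctrl_candidates)
        )
        snp_report["trait_vs_control"] = {
            "table_2x2": [list(r) for r in enr.table_2x2],
            "odds_ratio": enr.odds_ratio if enr.odds_ratio != float("inf") else "inf",
            "p_value": enr.p_value,
            "method": enr.method,
        }
    report["snp_mapping"] = snp_report

    # --- clustering and concordance ----------------------------------------
    deg_ids = {d.gene_id for d in degs}
    deg_genes: list[GeneRecord] = [g for g in genes if g.gene_id in deg_ids]

    clusters = cc.cluster_variants(candidates, config.gap_bp, config.min_cluster_size)
    sentinel_clusters = cc.cluster_variants(
        [v for v in candidates if v.is_sentinel], config.gap_bp, config.min_cluster_size
    )
    pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "chrom": c.chrom, "first_pos": c.first_pos,
             "last_pos": c.last_pos, "span_bp": c.span_bp, "n_snps": len(c.members)}
            for c in clusters
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    n_cl, n_deg_cl, pairs = cc.overlap_clusters_degs(clusters, deg_genes)
    prox = cc.variants_near_genes(candidates, deg_genes, config.windows_bp)
    near = cc.genes_near_contacts(deg_genes, dll_contacts_a, config.windows_bp)
    report["clusters"] = {
        "cluster_count": len(clusters),
        "sentinel_cluster_count": len(sentinel_clusters),
        "clusters_overlapping_deg": n_cl,
        "degs_overlapping_cluster": n_deg_cl,
        "cluster_deg_pairs": [list(p) for p in pairs],
    }
    report["concordance"] = {
        "variants_near_degs": [
            {"window_bp": p.window_bp, "unique_snps": p.unique_left_count,
             "unique_degs": p.unique_right_count}
            for p in prox
        ],
        "degs_near_dll_contacts": near,
    }

    # --- loop-anchored term enrichment --------------------------------------
    assign_a = en.assign_genes(set_a, genes, config.promoter_flank_bp)
    assign_b = en.assign_genes(set_b, genes, config.promoter_flank_bp)
    foreground = sorted({a.gene_id for a in assign_a})
    universe = sorted({a.gene_id for a in assign_a} | {a.gene_id for a in assign_b})
    results = en.enrich_terms(foreground, universe, terms, alpha=config.alpha)
    pd.DataFrame(
        [
            {"term_id": r.term_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p_raw": r.p_raw, "p_adj": r.p_adj,
             "significant": r.p_adj <= config.alpha}
            for r in results
        ]
    ).to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
    report["enrichment"] = {
        "foreground_size": len(foreground),
        "universe_size": len(universe),
        "terms_tested": len(results),
        "significant_terms": en.significant_terms(results, config.alpha),
    }

    ldio.write_report(report, outdir / "report.json")
    logger.info("pipeline done: report at %s", outdir / "report.json")
    return report
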