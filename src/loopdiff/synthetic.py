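"""Synthetic genomes, loop sets, variant tables, genes/DEGs and term sets.

Everything downstream is testable against recorded ground truth without any
download. The generator plants, on a multi-resolution anchor grid:

* two loop sets with exact fractions of fully shared loops, loops sharing a
  single anchor, and cell-type-unique loops (largest-remainder rounding);
* GWAS sentinels with LD-proxy clouds whose r² values straddle the selection
  threshold, a controlled fraction of sentinels inside loop anchors of cell
  type A, and a disjoint control trait with a lower in-anchor rate;
* tight proxy clouds for a subset of sentinels so positional SNP clusters
  exist, and spread clouds elsewhere so chains stay below the size filter;
* gene bodies with strand-aware TSSs, a DEG subset, DEG bodies planted over
  specific cluster spans;
* GMT term sets with a subset of terms enriched for a designated foreground.

Ground truth is re-derived at generation time by brute force (all-pairs
containment, union-find closure), never by the pipeline's own algorithms, so
truth-vs-pipeline comparisons stay two independent routes. Every stage draws
from ``default_rng([seed, stage_tag])``: regenerating under one seed is
byte-identical, per stage and end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as ldio
from .core import (
    ChromatinLoop,
    ConfigError,
    DEGRecord,
    GeneRecord,
    GenerationError,
    GenomicInterval,
    LoopSet,
    VariantRecord,
)

# stage tags for per-stage child generators
_STAGE_GENOME, _STAGE_LOOPS, _STAGE_VARIANTS, _STAGE_GENES, _STAGE_TERMS, _STAGE_ALLOC = range(6)


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    n_chromosomes: int = 8
    chrom_length_bp: int = 12_000_000
    anchor_resolutions_bp: tuple[int, ...] = (1000, 4000, 16000)
    n_loops_per_cell: int = 300
    frac_shared_loops: float = 0.2
    frac_shared_single_anchor: float = 0.1
    n_sentinels: int = 40
    proxies_per_sentinel: int = 10
    ld_r2_bounds: tuple[float, float] = (0.3, 1.0)
    proxy_window_bp: int = 100_000
    n_genes: int = 200
    frac_deg: float = 0.3
    n_terms: int = 30
    planted_enriched_terms: int = 3
    # variant-placement knobs required by the planting contract
    frac_sentinels_in_anchors: float = 0.15
    frac_clustered_sentinels: float = 0.5
    n_control_sentinels: int = 40
    control_frac_in_anchors: float = 0.02
    trait: str = "bone"
    control_trait: str = "control"
    n_planted_deg_overlaps: int = 5

    def __post_init__(self) -> None:
        fracs = {
            "frac_shared_loops": self.frac_shared_loops,
            "frac_shared_single_anchor": self.frac_shared_single_anchor,
            "frac_deg": self.frac_deg,
            "frac_sentinels_in_anchors": self.frac_sentinels_in_anchors,
            "frac_clustered_sentinels": self.frac_clustered_sentinels,
            "control_frac_in_anchors": self.control_frac_in_anchors,
        }
        for name, f in fracs.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"{name}={f} not in [0,1]")
        if self.frac_shared_loops + self.frac_shared_single_anchor > 1.0 + 1e-12:
            raise ConfigError("frac_shared_loops + frac_shared_single_anchor > 1")
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "n_loops_per_cell": self.n_loops_per_cell,
            "n_sentinels": self.n_sentinels,
            "proxies_per_sentinel": self.proxies_per_sentinel,
            "n_genes": self.n_genes,
            "n_terms": self.n_terms,
            "planted_enriched_terms": self.planted_enriched_terms,
            "n_control_sentinels": self.n_control_sentinels,
        }
        for name, c in counts.items():
            if c < 0:
                raise ConfigError(f"{name}={c} must be >= 0")
        res = tuple(self.anchor_resolutions_bp)
        if len(res) != len(set(res)) or any(r <= 0 for r in res):
            raise ConfigError("anchor resolutions must be positive and distinct")
        lo, hi = self.ld_r2_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"ld_r2_bounds {self.ld_r2_bounds} invalid")
        if self.n_chromosomes > 0 and self.chrom_length_bp <= 0:
            raise ConfigError("chrom_length_bp must be positive")
        if self.n_chromosomes > 0 and self.proxy_window_bp >= self.chrom_length_bp:
            raise ConfigError("proxy_window_bp must be smaller than a chromosome")
        if self.planted_enriched_terms > self.n_terms:
            raise ConfigError("planted_enriched_terms > n_terms")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TruthManifest:
    """Recorded ground truth of one synthetic dataset."""

    loop_class_by_id: dict[str, str] = field(default_factory=dict)
    snp_in_contact_by_id: dict[str, dict[str, bool]] = field(default_factory=dict)
    expected_cluster_memberships: list[list[str]] = field(default_factory=list)
    planted_deg_overlaps: dict[str, list[str]] = field(default_factory=dict)
    enriched_term_ids: list[str] = field(default_factory=list)
    term_foreground_gene_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        return cls.from_json(Path(path).read_text())


def largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Integer class counts summing to ``total``, largest-remainder rounding.

    Ties in the fractional part resolve to the earlier class.
    """
    if total < 0:
        raise ConfigError("total must be >= 0")
    quotas = [f * total for f in fractions]
    floors = [int(np.floor(q)) for q in quotas]
    short = total - sum(floors)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    for i in order[:short]:
        floors[i] += 1
    return floors


class _Allocator:
    """Hands out disjoint, spacer-separated regions across the genome.

    Regions are placed uniformly at random (seeded) with rejection on
    collision, so loops, variant clouds and gene bodies interleave along each
    chromosome the way features do in a real genome, while staying pairwise
    disjoint with at least ``spacer_bp`` between neighbours.
    """

    _MAX_ATTEMPTS = 500

    def __init__(
        self,
        genome: dict[str, int],
        spacer_bp: int = 12_000,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.genome = dict(genome)
        self.spacer_bp = spacer_bp
        self.rng = rng if rng is not None else np.random.default_rng(0)
        # per-chromosome sorted occupied intervals, spacer included
        self._used: dict[str, list[tuple[int, int]]] = {c: [] for c in self.genome}

    def _is_free(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        ivs = self._used[chrom]
        i = bisect.bisect_left(ivs, (start, start))
        if i > 0 and ivs[i - 1][1] > start:
            return False
        if i < len(ivs) and ivs[i][0] < end:
            return False
        return True

    def take(self, length_bp: int, align: int = 1, what: str = "region") -> tuple[str, int]:
        import bisect

        chroms = [c for c, L in self.genome.items() if L >= length_bp]
        if not chroms:
            raise GenerationError(
                f"cannot place {what} of {length_bp} bp: no chromosome long "
                f"enough (binding constraint: chrom_length_bp)"
            )
        for _ in range(self._MAX_ATTEMPTS):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            max_start = (self.genome[chrom] - length_bp) // align
            start = int(self.rng.integers(0, max_start + 1)) * align
            lo = max(0, start - self.spacer_bp)
            hi = min(self.genome[chrom], start + length_bp + self.spacer_bp)
            if self._is_free(chrom, lo, hi):
                bisect.insort(self._used[chrom], (lo, hi))
                return chrom, start
        raise GenerationError(
            f"cannot place {what} of {length_bp} bp after "
            f"{self._MAX_ATTEMPTS} attempts: genome territory exhausted "
            f"(binding constraint: total length vs requested feature count)"
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig) -> dict[str, int]:
    """Chromosome-size table: chr1..chrN, each ``chrom_length_bp`` long."""
    if config.n_chromosomes > 0 and config.chrom_length_bp <= 0:
        raise ConfigError("non-positive chromosome length")
    return {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chromosomes)
    }


# ---------------------------------------------------------------------------
# loop sets
# ---------------------------------------------------------------------------

def _make_loop(
    loop_id: str, chrom: str, start: int, res: int, k_right: int, score: float
) -> ChromatinLoop:
    return ChromatinLoop(
        loop_id=loop_id,
        anchor_left=GenomicInterval(chrom, start, start + res),
        anchor_right=GenomicInterval(chrom, start + k_right * res, start + (k_right + 1) * res),
        resolution_bp=res,
        score=score,
    )


def generate_loop_sets(
    config: SyntheticConfig,
    genome: dict[str, int],
    allocator: Optional[_Allocator] = None,
    manifest: Optional[TruthManifest] = None,
) -> tuple[LoopSet, LoopSet, TruthManifest]:
    """Two loop sets with exactly planted shared / single-anchor / unique classes."""
    rng = config._rng(_STAGE_LOOPS)
    alloc = allocator or _Allocator(genome, rng=config._rng(_STAGE_ALLOC))
    manifest = manifest or TruthManifest()
    n = config.n_loops_per_cell
    n_shared, n_single, n_unique = largest_remainder(
        n,
        [
            config.frac_shared_loops,
            config.frac_shared_single_anchor,
            1.0 - config.frac_shared_loops - config.frac_shared_single_anchor,
        ],
    )
    resolutions = tuple(sorted(config.anchor_resolutions_bp))
    loops_a: list[ChromatinLoop] = []
    loops_b: list[ChromatinLoop] = []

    def new_block(extra_bins: int, what: str) -> tuple[str, int, int, int, int]:
        res = int(rng.choice(resolutions))
        k1 = int(rng.integers(2, 7))
        k2 = k1 + 1 + int(rng.integers(0, 3)) if extra_bins else k1
        chrom, start = alloc.take((k2 + 1) * res, align=res, what=what)
        return chrom, start, res, k1, k2

    for i in range(n_shared):
        chrom, start, res, k1, _ = new_block(0, "shared loop")
        score = float(np.round(rng.uniform(1, 100), 3))
        a = _make_loop(f"A_{len(loops_a):06d}", chrom, start, res, k1, score)
        b = _make_loop(f"B_{len(loops_b):06d}", chrom, start, res, k1, score)
        loops_a.append(a)
        loops_b.append(b)
        manifest.loop_class_by_id[a.loop_id] = "shared"
        manifest.loop_class_by_id[b.loop_id] = "shared"

    for i in range(n_single):
        chrom, start, res, k1, k2 = new_block(1, "single-anchor loop pair")
        a = _make_loop(
            f"A_{len(loops_a):06d}", chrom, start, res, k1,
            float(np.round(rng.uniform(1, 100), 3)),
        )
        b = _make_loop(
            f"B_{len(loops_b):06d}", chrom, start, res, k2,
            float(np.round(rng.uniform(1, 100), 3)),
        )
        loops_a.append(a)
        loops_b.append(b)
        manifest.loop_class_by_id[a.loop_id] = "single_anchor"
        manifest.loop_class_by_id[b.loop_id] = "single_anchor"

    for cell, loops, cls in (("A", loops_a, "unique_A"), ("B", loops_b, "unique_B")):
        for i in range(n_unique):
            chrom, start, res, k1, _ = new_block(0, f"unique {cell} loop")
            lp = _make_loop(
                f"{cell}_{len(loops):06d}", chrom, start, res, k1,
                float(np.round(rng.uniform(1, 100), 3)),
            )
            loops.append(lp)
            manifest.loop_class_by_id[lp.loop_id] = cls

    set_a = LoopSet(cell_label="A", loops=tuple(loops_a))
    set_b = LoopSet(cell_label="B", loops=tuple(loops_b))
    return set_a, set_b, manifest


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _place_cloud(
    rng: np.random.Generator,
    config: SyntheticConfig,
    chrom: str,
    sentinel_pos: int,
    chrom_len: int,
    clustered: bool,
    used: dict[str, set[int]],
) -> list[tuple[int, float]]:
    """Proxy (pos, r²) pairs around one sentinel.

    Tight clouds (spacing 200-450 bp, r² safely above the 0.6 threshold) plant
    a retainable positional cluster; spread clouds (spacing > 5000 bp, r²
    uniform on the configured bounds straddling 0.6) plant none.
    """
    m = config.proxies_per_sentinel
    lo, hi = config.ld_r2_bounds
    out: list[tuple[int, float]] = []
    pos = sentinel_pos
    direction = 1
    for j in range(m):
        if clustered:
            step = int(rng.integers(200, 451))
            pos = pos + step
            r2 = float(np.round(rng.uniform(max(0.65, lo), hi), 4))
        else:
            max_step = max(5002, config.proxy_window_bp // max(1, m))
            step = int(rng.integers(5001, max_step + 1))
            # alternate sides of the sentinel
            direction = -direction
            offset = abs(out[-1][0] - sentinel_pos) + step if out else step
            pos = sentinel_pos + direction * offset
            r2 = float(np.round(rng.uniform(lo, hi), 4))
        if abs(pos - sentinel_pos) > config.proxy_window_bp or not (0 <= pos < chrom_len):
            raise GenerationError(
                f"proxy window {config.proxy_window_bp} bp too small for "
                f"{m} proxies around {chrom}:{sentinel_pos}"
            )
        if pos in used[chrom]:
            raise GenerationError(
                f"duplicate variant position {chrom}:{pos} — proxy window too dense"
            )
        used[chrom].add(pos)
        out.append((pos, r2))
    return out


def generate_variants(
    config: SyntheticConfig,
    genome: dict[str, int],
    loop_sets: tuple[LoopSet, LoopSet],
    allocator: Optional[_Allocator] = None,
    manifest: Optional[TruthManifest] = None,
) -> tuple[list[VariantRecord], TruthManifest]:
    """Sentinels + LD clouds for the study trait and a control trait.

    A planted fraction of study-trait sentinels sits inside loop anchors of
    cell type A; the control trait gets a lower in-anchor rate. In-contact
    truth per cell type is recorded by brute-force point-in-anchor checks;
    expected clusters by union-find closure over the selected candidates.
    """
    rng = config._rng(_STAGE_VARIANTS)
    alloc = allocator or _Allocator(genome, rng=config._rng(_STAGE_ALLOC))
    manifest = manifest or TruthManifest()
    set_a, set_b = loop_sets
    anchors_a = sorted({a for lp in set_a for a in lp.anchors})
    used: dict[str, set[int]] = {c: set() for c in genome}
    variants: list[VariantRecord] = []
    counter = 0

    def next_rsid() -> str:
        nonlocal counter
        counter += 1
        return f"rs{counter:06d}"

    def place_trait(
        trait: str, n_sent: int, frac_in_anchor: float, frac_clustered: float
    ) -> None:
        n_in = largest_remainder(n_sent, [frac_in_anchor, 1 - frac_in_anchor])[0]
        n_clustered = largest_remainder(n_sent, [frac_clustered, 1 - frac_clustered])[0]
        if n_in > 0 and not anchors_a:
            raise GenerationError("cannot plant in-anchor sentinels: no loops in set A")
        # at most one planted sentinel per loop, so tight clouds cannot chain
        if n_in > 0:
            loop_idx = rng.choice(len(set_a.loops), size=n_in, replace=False)
        for s in range(n_sent):
            if s < n_in:
                lp = set_a.loops[int(loop_idx[s])]
                anchor = lp.anchors[int(rng.integers(0, 2))]
                chrom = anchor.chrom
                pos = int(rng.integers(anchor.start, anchor.end))
                while pos in used[chrom]:
                    pos = int(rng.integers(anchor.start, anchor.end))
            else:
                width = 2 * config.proxy_window_bp + 1000
                chrom, start = alloc.take(width, what=f"{trait} sentinel cloud")
                pos = start + width // 2
            used[chrom].add(pos)
            rsid = next_rsid()
            variants.append(
                VariantRecord(
                    rsid=rsid,
                    chrom=chrom,
                    pos=pos,
                    trait=trait,
                    is_sentinel=True,
                    assoc_p=float(10 ** rng.uniform(-12, -7)),
                    ld_r2=1.0,
                )
            )
            clustered = s < n_clustered
            cloud = _place_cloud(
                rng, config, chrom, pos, genome[chrom], clustered, used
            )
            for ppos, r2 in cloud:
                variants.append(
                    VariantRecord(
                        rsid=next_rsid(),
                        chrom=chrom,
                        pos=ppos,
                        trait=trait,
                        is_sentinel=False,
                        assoc_p=float(10 ** rng.uniform(-8, -2)),
                        ld_r2=r2,
                        sentinel_rsid=rsid,
                    )
                )

    place_trait(
        config.trait, config.n_sentinels,
        config.frac_sentinels_in_anchors, config.frac_clustered_sentinels,
    )
    place_trait(
        config.control_trait, config.n_control_sentinels,
        config.control_frac_in_anchors, 0.0,
    )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.rsid))

    # brute-force in-contact truth, per cell type
    anchors_by_cell = {
        "A": anchors_a,
        "B": sorted({a for lp in set_b for a in lp.anchors}),
    }
    for v in variants:
        manifest.snp_in_contact_by_id[v.rsid] = {
            cell: any(a.contains(v.chrom, v.pos) for a in anchors)
            for cell, anchors in anchors_by_cell.items()
        }

    manifest.expected_cluster_memberships = _truth_clusters(
        variants, config, gap_bp=5000, min_size=10
    )
    return variants, manifest


def _truth_clusters(
    variants: Sequence[VariantRecord],
    config: SyntheticConfig,
    gap_bp: int,
    min_size: int,
) -> list[list[str]]:
    """Expected retained clusters via union-find over all candidate pairs.

    Candidates follow the selection rule (sentinel p < 1e-5; proxy r² > 0.6
    with surviving sentinel) applied to the study trait. Deliberately not the
    pipeline's chaining implementation.
    """
    surviving = {
        v.rsid for v in variants
        if v.is_sentinel and v.trait == config.trait and v.assoc_p < 1e-5
    }
    cands = [
        v for v in variants
        if v.trait == config.trait
        and (
            v.rsid in surviving
            or (not v.is_sentinel and v.sentinel_rsid in surviving and v.ld_r2 > 0.6)
        )
    ]
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if cands[i].chrom == cands[j].chrom and abs(cands[i].pos - cands[j].pos) <= gap_bp:
                parent[find(i)] = find(j)
    groups: dict[int, list[VariantRecord]] = {}
    for i, v in enumerate(cands):
        groups.setdefault(find(i), []).append(v)
    kept = [g for g in groups.values() if len(g) >= min_size]
    kept.sort(key=lambda g: (g[0].chrom, min(v.pos for v in g)))
    return [
        [v.rsid for v in sorted(g, key=lambda v: (v.pos, v.rsid))] for g in kept
    ]


# ---------------------------------------------------------------------------
# genes and DEGs
# ---------------------------------------------------------------------------

def generate_genes_and_deg(
    config: SyntheticConfig,
    genome: dict[str, int],
    cluster_memberships: Optional[Sequence[Sequence[str]]] = None,
    variants: Optional[Sequence[VariantRecord]] = None,
    allocator: Optional[_Allocator] = None,
    manifest: Optional[TruthManifest] = None,
) -> tuple[list[GeneRecord], list[DEGRecord], TruthManifest]:
    """Strand-aware gene bodies plus a planted DEG table.

    When cluster truth is supplied, up to ``n_planted_deg_overlaps`` DEG
    bodies are placed straddling cluster spans and the (cluster, gene)
    overlaps recorded.
    """
    rng = config._rng(_STAGE_GENES)
    alloc = allocator or _Allocator(genome, rng=config._rng(_STAGE_ALLOC))
    manifest = manifest or TruthManifest()
    clusters = list(cluster_memberships or [])
    pos_by_rsid = {v.rsid: (v.chrom, v.pos) for v in (variants or [])}

    n_deg = largest_remainder(config.n_genes, [config.frac_deg, 1 - config.frac_deg])[0]
    n_planted = min(config.n_planted_deg_overlaps, n_deg, len(clusters))

    bodies: list[tuple[str, int, int, bool]] = []  # (chrom, start, end, planted)
    for ci in range(n_planted):
        members = clusters[ci]
        chrom = pos_by_rsid[members[0]][0]
        first = min(pos_by_rsid[r][1] for r in members)
        last = max(pos_by_rsid[r][1] for r in members)
        start = max(0, first - int(rng.integers(1000, 3001)))
        end = last + int(rng.integers(1000, 3001))
        if end > genome[chrom]:
            raise GenerationError(f"planted DEG body exceeds {chrom} length")
        bodies.append((chrom, start, end, True))
    for _ in range(config.n_genes - n_planted):
        length = int(rng.integers(5_000, 30_001))
        chrom, start = alloc.take(length, what="gene body")
        bodies.append((chrom, start, start + length, False))

    order = sorted(range(len(bodies)), key=lambda i: (bodies[i][0], bodies[i][1], bodies[i][2]))
    genes: list[GeneRecord] = []
    planted_gene_ids: list[str] = []
    planted_cluster_of_gene: dict[str, int] = {}
    strands = rng.choice(["+", "-"], size=len(bodies))
    for rank, i in enumerate(order):
        chrom, start, end, planted = bodies[i]
        gid = f"gene_{rank:05d}"
        genes.append(GeneRecord(gene_id=gid, chrom=chrom, start=start, end=end,
                                strand=str(strands[rank])))
        if planted:
            planted_gene_ids.append(gid)
            planted_cluster_of_gene[gid] = i  # i < n_planted: cluster index

    # DEG set: all planted-overlap genes plus random others up to n_deg
    rest = [g.gene_id for g in genes if g.gene_id not in planted_gene_ids]
    extra = sorted(
        rng.choice(rest, size=n_deg - len(planted_gene_ids), replace=False).tolist()
    )
    deg_ids = sorted(planted_gene_ids + extra)
    degs = []
    for gid in deg_ids:
        magnitude = 0.5 + abs(float(rng.normal(0, 2)))
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        degs.append(
            DEGRecord(
                gene_id=gid,
                log_fc=float(np.round(sign * magnitude, 4)),
                p_adj=float(np.round(rng.uniform(1e-6, 0.049), 8)),
            )
        )

    for gid, ci in sorted(planted_cluster_of_gene.items()):
        cluster_id = f"cluster_{ci:05d}"
        manifest.planted_deg_overlaps.setdefault(cluster_id, []).append(gid)
    return genes, degs, manifest


# ---------------------------------------------------------------------------
# term sets
# ---------------------------------------------------------------------------

def generate_term_sets(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    foreground_gene_ids: Sequence[str],
    manifest: Optional[TruthManifest] = None,
) -> tuple[dict[str, list[str]], TruthManifest]:
    """GMT-style term sets with ``planted_enriched_terms`` enriched terms.

    Planted terms draw >= 80% of their members from the designated foreground
    list; background terms draw uniformly from the gene universe.
    """
    rng = config._rng(_STAGE_TERMS)
    manifest = manifest or TruthManifest()
    universe = [g.gene_id for g in genes]
    fg = [g for g in foreground_gene_ids if g in set(universe)]
    bg = sorted(set(universe) - set(fg))
    terms: dict[str, list[str]] = {}
    for t in range(config.n_terms):
        term_id = f"term_{t:04d}"
        planted = t < config.planted_enriched_terms
        if planted:
            size = int(rng.integers(10, 21))
            if size > len(universe):
                raise GenerationError(f"term size {size} exceeds gene universe")
            n_fg = min(len(fg), int(np.ceil(0.8 * size)))
            if n_fg == 0:
                raise GenerationError("no foreground genes to plant enrichment")
            members = sorted(rng.choice(fg, size=n_fg, replace=False).tolist())
            n_bg = min(size - n_fg, len(bg))
            if n_bg > 0:
                members += sorted(rng.choice(bg, size=n_bg, replace=False).tolist())
            manifest.enriched_term_ids.append(term_id)
        else:
            size = int(rng.integers(5, 41))
            if size > len(universe):
                raise GenerationError(f"term size {size} exceeds gene universe")
            members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        terms[term_id] = members
    manifest.term_foreground_gene_ids = sorted(fg)
    return terms, manifest


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """One fully generated study: files-on-disk equivalent, plus truth."""

    config: SyntheticConfig
    genome: dict[str, int]
    loop_set_a: LoopSet
    loop_set_b: LoopSet
    variants: list[VariantRecord]
    genes: list[GeneRecord]
    degs: list[DEGRecord]
    terms: dict[str, list[str]]
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every artifact as plain text; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "genome.chrom.sizes",
            "loops_a": outdir / "loops_A.bedpe",
            "loops_b": outdir / "loops_B.bedpe",
            "variants": outdir / "variants.tsv",
            "genes": outdir / "genes.tsv",
            "deg": outdir / "deg.tsv",
            "terms": outdir / "terms.gmt",
            "manifest": outdir / "truth_manifest.json",
        }
        ldio.write_chrom_sizes(self.genome, paths["chrom_sizes"])
        ldio.write_loops(self.loop_set_a, paths["loops_a"])
        ldio.write_loops(self.loop_set_b, paths["loops_b"])
        ldio.write_variant_table(self.variants, paths["variants"])
        ldio.write_gene_table(self.genes, paths["genes"])
        ldio.write_deg_table(self.degs, paths["deg"])
        ldio.write_gmt(self.terms, paths["terms"])
        self.manifest.write(paths["manifest"])
        return paths


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator stage under one seed with shared genome territory."""
    genome = generate_genome(config)
    alloc = _Allocator(genome, rng=config._rng(_STAGE_ALLOC))
    manifest = TruthManifest()
    set_a, set_b, manifest = generate_loop_sets(config, genome, alloc, manifest)
    variants, manifest = generate_variants(config, genome, (set_a, set_b), alloc, manifest)
    genes, degs, manifest = generate_genes_and_deg(
        config, genome, manifest.expected_cluster_memberships, variants, alloc, manifest
    )
    deg_ids = [d.gene_id for d in degs]
    terms, manifest = generate_term_sets(config, genes, deg_ids, manifest)
    return SyntheticDataset(
        config=config,
        genome=genome,
        loop_set_a=set_a,
        loop_set_b=set_b,
        variants=variants,
        genes=genes,
        degs=degs,
        terms=terms,
        manifest=manifest,
    )
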