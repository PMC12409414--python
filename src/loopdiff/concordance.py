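"""Positional SNP clustering and SNP/DEG/DLL concordance summaries.

Clustering follows merge semantics on sorted positions: variants within the
gap threshold (default 5000 bp) of the previous variant chain into one
cluster; chains with fewer than the minimum number of variants (default 10)
are discarded. The clustered region size is the inclusive first-to-last
distance. Concordance counts are "x unique left, y unique right" summaries at
distance windows {0, 50 kb, 200 kb, 1 Mb}; gene overlap uses the gene body.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from ._sweep import interval_overlap_join, point_in_interval_join
from .core import (
    ConfigError,
    GeneRecord,
    GenomicInterval,
    ProximitySummary,
    SNPCluster,
    VariantRecord,
)

DEFAULT_WINDOWS_BP = (0, 50_000, 200_000, 1_000_000)


def cluster_variants(
    candidates: Sequence[VariantRecord],
    gap_bp: int = 5000,
    min_size: int = 10,
) -> list[SNPCluster]:
    """Single-linkage chain variants within ``gap_bp``; drop small clusters.

    Input order is irrelevant (positions are sorted per chromosome first).
    Cluster ids are assigned in (chrom, first_pos) order.
    """
    if gap_bp < 0 or min_size < 0:
        raise ConfigError("gap_bp and min_size must be >= 0")
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in candidates:
        by_chrom.setdefault(v.chrom, []).append(v)

    clusters: list[SNPCluster] = []
    n = 0
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda v: (v.pos, v.rsid))
        chain: list[VariantRecord] = []
        for v in members + [None]:  # sentinel flushes the last chain
            if chain and (v is None or v.pos - chain[-1].pos > gap_bp):
                if len(chain) >= min_size:
                    clusters.append(
                        SNPCluster(
                            cluster_id=f"cluster_{n:05d}",
                            chrom=chrom,
                            members=tuple(m.rsid for m in chain),
                            first_pos=chain[0].pos,
                            last_pos=chain[-1].pos,
                        )
                    )
                    n += 1
                chain = []
            if v is not None:
                chain.append(v)
    return clusters


def overlap_clusters_degs(
    clusters: Sequence[SNPCluster], deg_genes: Sequence[GeneRecord]
) -> tuple[int, int, list[tuple[str, str]]]:
    """Cluster/DEG gene-body overlap pairs plus unique counts per side.

    A pair is recorded when the cluster's inclusive span intersects the gene
    body by >= 1 bp. Returns (unique_cluster_count, unique_deg_count, pairs).
    """
    left = [(c.chrom, c.interval.start, c.interval.end, c.cluster_id) for c in clusters]
    right = [(g.chrom, g.start, g.end, g.gene_id) for g in deg_genes]
    pairs = sorted(set(interval_overlap_join(left, right)))
    return len({c for c, _ in pairs}), len({g for _, g in pairs}), pairs


def _windowed_gene_interval(g: GeneRecord, window_bp: int) -> tuple[str, int, int, str]:
    return (g.chrom, max(0, g.start - window_bp), g.end + window_bp, g.gene_id)


def variants_near_genes(
    candidates: Sequence[VariantRecord],
    deg_genes: Sequence[GeneRecord],
    windows_bp: Sequence[int] = DEFAULT_WINDOWS_BP,
) -> list[ProximitySummary]:
    """Distinct variants within ±window of a DEG body, and DEGs so hit.

    Window 0 means inside the gene body; window-extended starts are floored
    at 0. Counts are non-decreasing in window size.
    """
    points = [(v.chrom, v.pos, v.rsid) for v in candidates]
    out = []
    for w in windows_bp:
        if w < 0:
            raise ConfigError("negative window")
        ivs = [_windowed_gene_interval(g, w) for g in deg_genes]
        pairs = point_in_interval_join(points, ivs)
        out.append(
            ProximitySummary(
                window_bp=w,
                unique_left_count=len({r for r, _ in pairs}),
                unique_right_count=len({g for _, g in pairs}),
            )
        )
    return out


def genes_near_contacts(
    deg_genes: Sequence[GeneRecord],
    dll_contacts: Sequence[GenomicInterval],
    windows_bp: Sequence[int] = DEFAULT_WINDOWS_BP,
) -> list[dict]:
    """Per window, "x of y" DEGs whose body lies within ±window of a contact.

    x counts distinct DEGs intersecting some contact widened by the window;
    y is the fixed DEG total (the denominator convention is configurable at
    the pipeline level but defaults to the full DEG list).
    """
    left = [(g.chrom, g.start, g.end, g.gene_id) for g in deg_genes]
    y = len({g.gene_id for g in deg_genes})
    out = []
    for w in windows_bp:
        if w < 0:
            raise ConfigError("negative window")
        right = [
            (c.chrom, max(0, c.start - w), c.end + w, i)
            for i, c in enumerate(dll_contacts)
        ]
        x = len({g for g, _ in interval_overlap_join(left, right)})
        out.append({"window_bp": int(w), "deg_in_window": x, "deg_total": y})
    return out
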