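"""Loop-to-gene assignment and hypergeometric gene-set over-representation.

Each loop is assigned the single gene whose promoter window (TSS ± flank,
strand-aware) is nearest to either anchor; distance 0 when an anchor
intersects the window, ties broken by lexicographic gene_id. The foreground
loop-gene list of one cell type is then tested term-by-term against a
background universe with the upper-tail hypergeometric test and
Benjamini–Hochberg correction; terms are generic gene sets (GMT), with no
ontology-graph propagation.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    ChromatinLoop,
    GeneAssignment,
    GeneRecord,
    GenomicInterval,
    LoopSet,
    TermEnrichment,
    ValidationError,
)


def promoter_window(gene: GeneRecord, flank_bp: int = 1000) -> GenomicInterval:
    """Promoter = [TSS - flank, TSS + flank + 1), strand-aware, floored at 0."""
    tss = gene.tss
    return GenomicInterval(gene.chrom, max(0, tss - flank_bp), tss + flank_bp + 1)


def assign_gene_to_loop(
    loop: ChromatinLoop,
    genes: Sequence[GeneRecord],
    promoter_flank_bp: int = 1000,
) -> Optional[GeneAssignment]:
    """Assign the gene with the closest promoter to the loop, or None.

    Distance is the minimum over both anchors of the bp gap to the promoter
    window (0 on intersection). Only genes on the loop's chromosome are
    eligible; equidistant genes resolve to the smaller gene_id.
    """
    best: Optional[tuple[int, str]] = None
    for g in genes:
        if g.chrom != loop.chrom:
            continue
        win = promoter_window(g, promoter_flank_bp)
        dist = min(anchor.gap_to(win) for anchor in loop.anchors)
        key = (dist, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return GeneAssignment(loop_id=loop.loop_id, gene_id=best[1], distance_bp=best[0])


def assign_genes(
    loop_set: LoopSet, genes: Sequence[GeneRecord], promoter_flank_bp: int = 1000
) -> list[GeneAssignment]:
    """One nearest-promoter gene assignment per loop (loops with no gene on
    their chromosome are skipped)."""
    out = []
    for lp in loop_set:
        a = assign_gene_to_loop(lp, genes, promoter_flank_bp)
        if a is not None:
            out.append(a)
    return out


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    N genes in the universe, K of them in the term, n drawn (the foreground);
    computed via the stable survival function, exact for these sizes.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order of input preserved."""
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    if len(p_values) == 0:
        return []
    return [float(q) for q in multipletests(list(p_values), method="fdr_bh")[1]]


def enrich_terms(
    foreground_genes: Sequence[str],
    universe_genes: Sequence[str],
    term_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[TermEnrichment]:
    """Hypergeometric over-representation of each term in the foreground.

    Term memberships are intersected with the universe before testing; terms
    with no universe overlap (K = 0) are untestable and omitted. Rows are
    sorted by (p_adj, term_id); significance is p_adj <= alpha.
    """
    universe = set(universe_genes)
    fg = set(foreground_genes)
    strays = sorted(fg - universe)
    if strays:
        raise ValidationError(f"foreground genes not in universe: {strays}")
    N, n = len(universe), len(fg)

    rows: list[tuple[str, int, int, float]] = []
    for term_id in sorted(term_sets):
        members = set(term_sets[term_id]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        rows.append((term_id, k, K, hypergeometric_pvalue(k, K, n, N)))
    if not rows:
        return []
    adjusted = bh_adjust([r[3] for r in rows])
    out = [
        TermEnrichment(term_id=t, k=k, K=K, n=n, N=N, p_raw=p, p_adj=q)
        for (t, k, K, p), q in zip(rows, adjusted)
    ]
    out.sort(key=lambda r: (r.p_adj, r.term_id))
    return out


def significant_terms(
    results: Sequence[TermEnrichment], alpha: float = 0.05
) -> list[str]:
    return [r.term_id for r in results if r.p_adj <= alpha]
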