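"""Candidate-variant selection, mapping to loop contacts, and enrichment.

Candidates are GWAS sentinels passing the association threshold plus their LD
proxies above the r² threshold; both thresholds are strict inequalities
(p < 1e-5, r² > 0.6). Mapping to contact regions is point-in-interval in
half-open coordinates via a sweep line; counting follows the
"unique SNPs within unique contacts" convention — a variant inside two
overlapping contacts yields two hits but one unique rsID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from ._sweep import point_in_interval_join
from .core import (
    ContactHit,
    EnrichmentResult,
    GenomicInterval,
    ValidationError,
    VariantRecord,
)


@dataclass
class CandidateSelection:
    """Thresholds and realized counts of candidate selection."""

    assoc_p_threshold: float = 1e-5
    ld_r2_threshold: float = 0.6
    sentinel_count: int = 0
    candidate_count: int = 0


def select_candidates(
    variants: Sequence[VariantRecord], selection: CandidateSelection | None = None
) -> tuple[list[VariantRecord], CandidateSelection]:
    """Apply strict association and LD thresholds.

    Sentinels are kept iff assoc_p < threshold; a proxy is kept iff its
    sentinel survives AND its ld_r2 > threshold. A proxy whose sentinel_rsid
    is absent from the table is an error.
    """
    sel = selection or CandidateSelection()
    sentinels = {v.rsid: v for v in variants if v.is_sentinel}
    surviving = {
        rsid for rsid, v in sentinels.items() if v.assoc_p < sel.assoc_p_threshold
    }
    candidates: list[VariantRecord] = []
    for v in variants:
        if v.is_sentinel:
            if v.rsid in surviving:
                candidates.append(v)
            continue
        if v.sentinel_rsid is None or v.sentinel_rsid not in sentinels:
            raise ValidationError(
                f"proxy {v.rsid} references missing sentinel {v.sentinel_rsid!r}"
            )
        if v.sentinel_rsid in surviving and v.ld_r2 > sel.ld_r2_threshold:
            candidates.append(v)
    sel.sentinel_count = sum(1 for v in candidates if v.is_sentinel)
    sel.candidate_count = len(candidates)
    return candidates, sel


def map_variants_to_contacts(
    candidates: Sequence[VariantRecord],
    contacts: Sequence[GenomicInterval],
    cell_label: str = "",
) -> tuple[list[ContactHit], int, int]:
    """All (variant, contact) containment pairs, plus unique counts.

    Sweep-line join, O((n+m) log(n+m) + hits). Returns (hits,
    unique_snp_count, unique_contact_count); counts are invariant to input
    order and row duplication.
    """
    points = [(v.chrom, v.pos, v.rsid) for v in candidates]
    uniq_contacts = sorted(set(contacts))
    ivs = [(c.chrom, c.start, c.end, i) for i, c in enumerate(uniq_contacts)]
    pairs = point_in_interval_join(points, ivs)
    hits = [
        ContactHit(rsid=rsid, contact=uniq_contacts[i], cell_label=cell_label)
        for rsid, i in pairs
    ]
    hits.sort(key=lambda h: (h.contact.chrom, h.contact.start, h.contact.end, h.rsid))
    unique_snps = len({h.rsid for h in hits})
    unique_contacts_hit = len({h.contact for h in hits})
    return hits, unique_snps, unique_contacts_hit


def trait_enrichment_test(
    hits_trait: int, total_trait: int, hits_control: int, total_control: int
) -> EnrichmentResult:
    """Two-sided Fisher's exact test: in-contact incidence, trait vs control.

    The 2x2 table is [[hits_trait, misses_trait], [hits_control,
    misses_control]]; the odds ratio is the cross-product, infinite on a zero
    denominator.
    """
    if not (0 <= hits_trait <= total_trait) or not (0 <= hits_control <= total_control):
        raise ValidationError("hits exceed totals in enrichment test")
    if total_trait == 0 or total_control == 0:
        raise ValidationError("empty margin in enrichment test")
    a, b = hits_trait, total_trait - hits_trait
    c, d = hits_control, total_control - hits_control
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table_2x2=((a, b), (c, d)),
        odds_ratio=odds,
        p_value=min(1.0, p),
        method="fisher_exact_two_sided",
    )


def fraction_in_contacts(
    unique_snp_hits: int, total_candidates: int
) -> tuple[float, int]:
    """Percentage of candidate variants inside loop contacts.

    Returns (raw percentage, nearest-integer percentage).
    """
    if total_candidates <= 0:
        raise ValidationError("total_candidates must be > 0")
    if not (0 <= unique_snp_hits <= total_candidates):
        raise ValidationError("hits outside [0, total]")
    pct = 100.0 * unique_snp_hits / total_candidates
    return pct, int(round(pct))
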