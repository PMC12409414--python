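"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (`[start, end)`), BED-native.
Chromosome names are normalized to the ``chrN`` dialect on construction of
I/O records; the types here only require a non-empty name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence


class LoopdiffError(Exception):
    """Base class for all package errors."""


class ValidationError(LoopdiffError):
    """An input record violates a structural invariant."""


class ConfigError(LoopdiffError):
    """A configuration value is out of range or inconsistent."""


class GenerationError(LoopdiffError):
    """The synthetic generator cannot satisfy the requested layout."""


_CHROM_RE = re.compile(r"^chr", re.IGNORECASE)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chrN`` dialect.

    ``"1"`` -> ``"chr1"``, ``"Chr1"`` -> ``"chr1"``, ``"chrX"`` unchanged.
    """
    name = str(name).strip()
    if not name:
        raise ValidationError("empty chromosome name")
    stripped = _CHROM_RE.sub("", name)
    return f"chr{stripped}"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval with empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Point containment: ``pos in [start, end)``."""
        return self.chrom == chrom and self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """bp gap between two intervals on one chromosome; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValidationError("gap between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def widened(self, flank_bp: int) -> "GenomicInterval":
        """Interval widened by ``flank_bp`` on each side, floored at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - flank_bp), self.end + flank_bp)


@dataclass(frozen=True)
class ChromatinLoop:
    """A cis chromatin loop: two ordered anchors on one chromosome.

    Each anchor is one "contact region" of the loop; ``resolution_bp`` is the
    call resolution (anchor bin size) the loop was detected at.
    """

    loop_id: str
    anchor_left: GenomicInterval
    anchor_right: GenomicInterval
    resolution_bp: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.anchor_left.chrom != self.anchor_right.chrom:
            raise ValidationError(
                f"loop {self.loop_id}: inter-chromosomal anchors "
                f"({self.anchor_left.chrom} vs {self.anchor_right.chrom})"
            )
        if self.anchor_left.start > self.anchor_right.start:
            raise ValidationError(
                f"loop {self.loop_id}: anchors not canonically ordered"
            )
        if self.resolution_bp <= 0:
            raise ValidationError(f"loop {self.loop_id}: non-positive resolution")

    @property
    def chrom(self) -> str:
        return self.anchor_left.chrom

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor_left, self.anchor_right)

    def on_grid(self) -> bool:
        """True if both anchors are resolution-aligned bins of width resolution_bp."""
        r = self.resolution_bp
        return all(
            a.start % r == 0 and a.length == r for a in self.anchors
        )


@dataclass(frozen=True)
class LoopSet:
    """All loop calls for one cell type."""

    cell_label: str
    loops: tuple[ChromatinLoop, ...]

    def __post_init__(self) -> None:
        ids = [lp.loop_id for lp in self.loops]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValidationError(
                f"loop set {self.cell_label!r}: duplicate loop ids {sorted(dups)}"
            )

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    @property
    def resolutions_present(self) -> frozenset[int]:
        return frozenset(lp.resolution_bp for lp in self.loops)


@dataclass(frozen=True)
class DLLRecord:
    """Cross-cell-type matching status of one loop.

    ``match_class`` is ``shared_loop`` (both anchors match a loop in the other
    cell type), ``shared_single_anchor`` (exactly one anchor matches) or
    ``unique`` — the differential loop locus (DLL) class.
    """

    loop_id: str
    cell_label: str
    match_class: str
    matched_loop_id: Optional[str] = None

    _CLASSES = ("shared_loop", "shared_single_anchor", "unique")

    def __post_init__(self) -> None:
        if self.match_class not in self._CLASSES:
            raise ValidationError(f"unknown match class {self.match_class!r}")
        if self.match_class == "shared_loop" and self.matched_loop_id is None:
            raise ValidationError(
                f"loop {self.loop_id}: shared_loop requires matched_loop_id"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A point variant with trait, sentinel status, and LD to its sentinel."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    is_sentinel: bool
    assoc_p: float
    ld_r2: float
    sentinel_rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"{self.rsid}: negative position")
        if not (0.0 < self.assoc_p <= 1.0):
            raise ValidationError(f"{self.rsid}: assoc_p {self.assoc_p} not in (0,1]")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValidationError(f"{self.rsid}: ld_r2 {self.ld_r2} not in [0,1]")
        if self.is_sentinel and self.ld_r2 != 1.0:
            raise ValidationError(
                f"{self.rsid}: sentinel variant must have ld_r2 = 1, got {self.ld_r2}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with strand; TSS is ``start`` on '+' and ``end - 1`` on '-'."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.gene_id}: invalid gene body")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene (consumed, never computed here)."""

    gene_id: str
    log_fc: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_adj <= 1.0):
            raise ValidationError(f"{self.gene_id}: p_adj {self.p_adj} not in (0,1]")


@dataclass(frozen=True)
class SNPCluster:
    """A maximal chain of variants with consecutive gaps <= the merge distance."""

    cluster_id: str
    chrom: str
    members: tuple[str, ...]
    first_pos: int
    last_pos: int

    def __post_init__(self) -> None:
        if self.last_pos < self.first_pos:
            raise ValidationError(f"{self.cluster_id}: last_pos < first_pos")
        if not self.members:
            raise ValidationError(f"{self.cluster_id}: empty cluster")

    @property
    def span_bp(self) -> int:
        """Inclusive first-to-last distance, as the clustered region size."""
        return self.last_pos - self.first_pos

    @property
    def interval(self) -> GenomicInterval:
        """Half-open interval covering the inclusive span: [first, last+1)."""
        return GenomicInterval(self.chrom, self.first_pos, self.last_pos + 1)


@dataclass(frozen=True)
class ContactHit:
    """One (variant, contact region) containment pair."""

    rsid: str
    contact: GenomicInterval
    cell_label: str


@dataclass(frozen=True)
class ProximitySummary:
    """Distinct-variant / distinct-gene counts at one distance window."""

    window_bp: int
    unique_left_count: int
    unique_right_count: int

    def __post_init__(self) -> None:
        if self.window_bp < 0 or self.unique_left_count < 0 or self.unique_right_count < 0:
            raise ValidationError("negative value in proximity summary")


@dataclass(frozen=True)
class GeneAssignment:
    """The gene whose promoter (±flank around the TSS) is closest to a loop."""

    loop_id: str
    gene_id: str
    distance_bp: int

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValidationError("negative assignment distance")


@dataclass(frozen=True)
class TermEnrichment:
    """Hypergeometric over-representation of one gene-set term.

    k: foreground genes in the term; K: term size within the universe;
    n: foreground size; N: universe size.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValidationError(f"term {self.term_id}: inconsistent counts")
        if self.p_adj + 1e-12 < self.p_raw:
            raise ValidationError(f"term {self.term_id}: p_adj < p_raw")


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 trait-vs-control contact-enrichment test outcome."""

    table_2x2: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if any(c < 0 for row in self.table_2x2 for c in row):
            raise ValidationError("negative count in 2x2 table")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} not in (0,1]")
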