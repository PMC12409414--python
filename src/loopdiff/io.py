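"""Readers and writers for every external format the pipeline touches.

One coordinate convention rules in memory: 0-based, half-open. BEDPE, BED and
chrom.sizes are already 0-based half-open on disk. Variant tables are 0-based
when the position column is named ``pos``; a table exported from a 1-based
source can instead carry ``pos_1based``, which is shifted on read. Chromosome
names are normalized to ``chrN`` on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    ChromatinLoop,
    DEGRecord,
    GeneRecord,
    GenomicInterval,
    LoopSet,
    ValidationError,
    VariantRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

VARIANT_COLUMNS = ["rsid", "chrom", "pos", "trait", "is_sentinel", "assoc_p", "ld_r2"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
DEG_COLUMNS = ["gene_id", "log_fc", "p_adj"]


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_loops(path: str | Path, resolution_bp: int, cell_label: str = "") -> LoopSet:
    """Read a 6+ column BEDPE file of cis loop calls.

    Anchors are canonicalized (left anchor starts first) and duplicate rows
    collapsed; the number of collapsed duplicates is logged. Inter-chromosomal
    rows are rejected with their line number.
    """
    path = Path(path)
    loops: dict[tuple, ChromatinLoop] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: BEDPE row has {len(fields)} columns, need >= 6"
                )
            try:
                c1, s1, e1 = normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                c2, s2, e2 = normalize_chrom(fields[3]), int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if c1 != c2:
                raise ValidationError(
                    f"{path}:{lineno}: inter-chromosomal row ({c1} vs {c2}) rejected"
                )
            if s1 >= e1 or s2 >= e2:
                raise ValidationError(f"{path}:{lineno}: anchor with start >= end")
            score = None
            if len(fields) >= 8 and fields[7] not in (".", ""):
                score = float(fields[7])
            a = GenomicInterval(c1, s1, e1)
            b = GenomicInterval(c2, s2, e2)
            if b.start < a.start or (b.start == a.start and b.end < a.end):
                a, b = b, a
            key = (a.chrom, a.start, a.end, b.start, b.end)
            if key in loops:
                n_dup += 1
                continue
            loops[key] = ChromatinLoop(
                loop_id=f"{cell_label or path.stem}_{len(loops):06d}",
                anchor_left=a,
                anchor_right=b,
                resolution_bp=resolution_bp,
                score=score,
            )
    if n_dup:
        logger.info("read_loops(%s): collapsed %d duplicate rows", path, n_dup)
    return LoopSet(cell_label=cell_label or path.stem, loops=tuple(loops.values()))


def write_loops(loop_set: LoopSet, path: str | Path) -> None:
    """Write a loop set as 8-column BEDPE (name and score in columns 7-8)."""
    with open(Path(path), "w") as fh:
        for lp in loop_set:
            score = "." if lp.score is None else repr(lp.score)
            fh.write(
                "\t".join(
                    [
                        lp.anchor_left.chrom,
                        str(lp.anchor_left.start),
                        str(lp.anchor_left.end),
                        lp.anchor_right.chrom,
                        str(lp.anchor_right.start),
                        str(lp.anchor_right.end),
                        lp.loop_id,
                        score,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED3 intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: BED row needs >= 3 columns")
            try:
                out.append(
                    GenomicInterval(normalize_chrom(fields[0]), int(fields[1]), int(fields[2]))
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Variant / gene / DEG TSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV; returns records sorted by (chrom, pos).

    The position column is ``pos`` (0-based) or ``pos_1based`` (shifted down
    by one on read). Duplicate rsIDs are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "trait": str})
    one_based = "pos_1based" in df.columns
    required = [c for c in VARIANT_COLUMNS if c != "pos"] + (
        ["pos_1based"] if one_based else ["pos"]
    )
    _require_columns(df, required, path)
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate rsID(s) {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        pos = int(getattr(row, "pos_1based") - 1) if one_based else int(row.pos)
        sentinel_rsid = getattr(row, "sentinel_rsid", None)
        if pd.isna(sentinel_rsid):
            sentinel_rsid = None
        records.append(
            VariantRecord(
                rsid=str(row.rsid),
                chrom=normalize_chrom(row.chrom),
                pos=pos,
                trait=str(row.trait),
                is_sentinel=bool(row.is_sentinel),
                assoc_p=float(row.assoc_p),
                ld_r2=float(row.ld_r2),
                sentinel_rsid=None if sentinel_rsid is None else str(sentinel_rsid),
            )
        )
    records.sort(key=lambda v: (v.chrom, v.pos, v.rsid))
    return records


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "rsid": v.rsid,
            "chrom": v.chrom,
            "pos": v.pos,
            "trait": v.trait,
            "is_sentinel": v.is_sentinel,
            "assoc_p": v.assoc_p,
            "ld_r2": v.ld_r2,
            "sentinel_rsid": "" if v.sentinel_rsid is None else v.sentinel_rsid,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["sentinel_rsid"]).to_csv(
        Path(path), sep="\t", index=False
    )


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    _require_columns(df, GENE_COLUMNS, path)
    genes = [
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=normalize_chrom(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path}: duplicate gene_id(s)")
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
             "strand": g.strand}
            for g in genes
        ],
        columns=GENE_COLUMNS,
    ).to_csv(Path(path), sep="\t", index=False)


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _require_columns(df, DEG_COLUMNS, path)
    return [
        DEGRecord(gene_id=str(r.gene_id), log_fc=float(r.log_fc), p_adj=float(r.p_adj))
        for r in df.itertuples(index=False)
    ]


def write_deg_table(degs: Iterable[DEGRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": d.gene_id, "log_fc": d.log_fc, "p_adj": d.p_adj} for d in degs],
        columns=DEG_COLUMNS,
    ).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets, chrom.sizes
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT: one term per line, ``name<TAB>description<TAB>gene...``."""
    terms: dict[str, list[str]] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT row needs >= 3 columns")
            name = fields[0]
            if name in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term {name!r}")
            terms[name] = [g for g in fields[2:] if g]
    return terms


def write_gmt(terms: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, genes in terms.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            name, size = line.split("\t")[:2]
            sizes[normalize_chrom(name)] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------

def write_report(results: Mapping, path: str | Path) -> None:
    """Write the stage-keyed pipeline report as deterministic JSON."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, **results}
    try:
        text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=False)
    except (TypeError, ValueError) as exc:
        bad = _find_unserializable(doc)
        raise ValidationError(f"unserializable report value at key {bad!r}: {exc}") from exc
    Path(path).write_text(text + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _find_unserializable(obj, prefix: str = "") -> str:
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            try:
                json.dumps(v, allow_nan=False)
            except (TypeError, ValueError):
                return _find_unserializable(v, f"{prefix}.{k}" if prefix else str(k))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            try:
                json.dumps(v, allow_nan=False)
            except (TypeError, ValueError):
                return _find_unserializable(v, f"{prefix}[{i}]")
    return prefix or "<root>"
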