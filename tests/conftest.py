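from __future__ import annotations

import numpy as np
import pytest

from loopdiff.core import ChromatinLoop, GenomicInterval, LoopSet, VariantRecord
from loopdiff.synthetic import SyntheticConfig, generate_dataset

# compact study for module tests: same structure, faster to generate
SMALL = dict(
    n_chromosomes=4,
    chrom_length_bp=6_000_000,
    n_loops_per_cell=60,
    n_sentinels=12,
    n_control_sentinels=12,
    n_genes=60,
    n_terms=20,
    planted_enriched_terms=2,
    n_planted_deg_overlaps=3,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SyntheticConfig(seed=7, **SMALL))


def random_loop_set(rng: np.random.Generator, cell: str, n: int, *,
                    n_chrom: int = 2, chrom_len: int = 200_000,
                    resolutions=(1000, 4000)) -> LoopSet:
    """Unconstrained random loops (overlaps and anchor reuse allowed)."""
    loops = []
    seen = set()
    while len(loops) < n:
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        res = int(rng.choice(resolutions))
        max_bin = chrom_len // res - 1
        b1, b2 = sorted(rng.integers(0, max_bin, size=2))
        if b1 == b2:
            continue
        key = (chrom, res, int(b1), int(b2))
        if key in seen:
            continue
        seen.add(key)
        loops.append(
            ChromatinLoop(
                loop_id=f"{cell}{len(loops):04d}",
                anchor_left=GenomicInterval(chrom, int(b1) * res, (int(b1) + 1) * res),
                anchor_right=GenomicInterval(chrom, int(b2) * res, (int(b2) + 1) * res),
                resolution_bp=res,
            )
        )
    return LoopSet(cell_label=cell, loops=tuple(loops))


def random_variants(rng: np.random.Generator, n: int, *, n_chrom: int = 2,
                    chrom_len: int = 200_000, trait: str = "t") -> list[VariantRecord]:
    out = []
    positions = set()
    while len(out) < n:
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        pos = int(rng.integers(0, chrom_len))
        if (chrom, pos) in positions:
            continue
        positions.add((chrom, pos))
        out.append(
            VariantRecord(
                rsid=f"rs{len(out):05d}", chrom=chrom, pos=pos, trait=trait,
                is_sentinel=True, assoc_p=1e-8, ld_r2=1.0,
            )
        )
    return out


def random_intervals(rng: np.random.Generator, n: int, *, n_chrom: int = 2,
                     chrom_len: int = 200_000, max_len: int = 5000) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, chrom_len - max_len))
        out.append(GenomicInterval(chrom, start, start + int(rng.integers(1, max_len))))
    return out
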