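# Methods

## Coordinate and matching conventions

All intervals are 0-based half-open (`[start, end)`); variant positions are
points in the same system (a `pos_1based` column is shifted on read).
Chromosome names are normalized to `chrN`. A loop is two same-chromosome
anchors stored in canonical order (left anchor starts first); trans loops are
rejected at parse time, as the analysis is restricted to cis looping.

Loop calling itself is out of scope: the package consumes called loops
(BEDPE, one set per cell type, one call resolution per file). When one loop
is called at several resolutions with identical anchor coordinates,
`merge_resolutions` keeps the record with the smallest resolution — the most
precise anchors. Published analyses that pool multi-scale calls rarely state
their dedup rule; this one is a documented package choice, configurable by
simply not merging.

## Loop classification (DLL)

Two called loops "match at an anchor" when the anchor intervals overlap by
≥ 1 bp after each is widened by `slack_bins × min(resolution_a, resolution_b)`
on each side; `slack_bins = 0` (the default) means raw overlap. A loop is

* `shared_loop` — some loop in the other set matches left-to-left **and**
  right-to-right;
* `shared_single_anchor` — not shared, but at least one anchor (either end)
  matches some anchor in the other set: one end keeps its contact while the
  other goes elsewhere;
* `unique` — no anchor matches: the differential loop locus class.

Exact-coordinate equality would be too brittle across call resolutions, which
is why matching is overlap-based with a slack knob. When several partners
qualify, the reported `matched_loop_id` maximizes summed anchor overlap, ties
broken by smallest (chrom, start, id) — purely for deterministic output.
Classification is presence/absence set algebra on called loops; it never
re-tests contact-matrix counts. Shared-loop counts are symmetric between the
two directions, the three classes partition each set, and the shared count is
non-decreasing in `slack_bins` (all property-tested).

The implementation joins widened anchors with an event-queue sweep line
(closes before opens before point queries at equal positions, which encodes
the half-open convention); tests compare it against an independent O(n·m)
all-pairs oracle.

## Regional loop-count test

For "x loops observed in one cell type vs y in the other at a locus" the
default test is the exact binomial: under the null each of the n = x + y
loops is equally likely to come from either cell type; the p-value doubles
the smaller tail of Binomial(n, 0.5) and caps at 1. A 1-df chi-square
goodness-of-fit is available as `method="chi2"`. For (22, 7) the binomial
gives 0.00813, matching the precedent this analysis follows; for (6, 3) it
gives 0.5078 where that precedent prints .3270 — no standard two-sample count
test we tried reproduces all published regional p-values simultaneously, so
the binomial is the documented default and the discrepancy is left visible
rather than tuned away.

## Candidate selection and contact mapping

Thresholds are strict inequalities, exactly as usually printed: sentinels
kept iff association p < 1 × 10⁻⁵; proxies kept iff their sentinel survives
and LD r² > 0.6. A proxy referencing an absent sentinel is an error, not a
silent drop. Mapping candidates into contact regions is a sweep-line
point-in-interval join, O((n+m) log(n+m) + hits); a variant inside two
overlapping contacts yields two hits but one unique rsID, matching the
"unique SNPs within unique contacts" counting convention. The headline
percentage is 100 × unique in-contact SNPs / total candidates, reported raw
and rounded to the nearest integer percent. Trait-vs-control contact
enrichment is a two-sided Fisher's exact test on the 2×2 in-contact ×
trait/control table, odds ratio as the cross-product (infinite on a zero
denominator).

## SNP clustering and concordance

Clustering is single-linkage chaining on position-sorted candidates
(BEDTools-merge semantics): a new cluster starts when the gap to the previous
variant exceeds 5000 bp; chains with fewer than 10 members are discarded.
The clustered region size is the inclusive first-to-last distance
(`last_pos − first_pos`); for overlap tests the cluster interval is
`[first, last + 1)` in half-open coordinates. Chaining on sorted points
equals the pairwise union-find closure, which is exactly how the test oracle
recomputes it.

Cluster–DEG and variant–DEG overlap use the gene **body** (not the TSS),
because "variants within DEGs" reads as gene-body containment; window
summaries extend gene bodies (or DLL contacts) by ±{0, 50, 200, 1000} kb
with starts floored at zero, and count distinct entities on each side. All
window counts are monotone non-decreasing in the window. In "x of y DEGs
near a contact" summaries, y is the fixed DEG total: a window-dependent
denominator is not derivable from a fixed DEG list, so the fixed total is
the default and the only mode the report emits.

## Loop-anchored term enrichment

Each loop is assigned the single gene whose promoter window
`[TSS − 1 kb, TSS + 1 kb + 1)` (strand-aware TSS: `start` on +, `end − 1` on
−) is nearest to either anchor; distance is the bp gap, 0 on intersection,
ties to the lexicographically smaller gene id. The foreground is the
loop-gene list of cell type A; the universe is genes assigned to any loop in
either cell type (the closest reading of "tested against the other cell
type's background list"; both lists are arguments, so any other universe is a
one-line change). Each GMT term is intersected with the universe (K = 0
terms are untestable and omitted) and tested with the exact hypergeometric
upper tail P(X ≥ k) via the stable survival function; Benjamini–Hochberg
step-up correction, significance at p_adj ≤ 0.05. Terms are flat gene sets —
no ontology-graph propagation.

Note the BH step-up is *not* idempotent in general (adjusting `[1.0, 0.25]`
gives `[1.0, 0.5]`; adjusting again gives `[1.0, 1.0]`), so the tested
invariants are the definitional ones: equality with the literal step-up,
monotonicity after sorting, adjusted ≥ raw.

## Synthetic study design

The generator emulates the structure of a two-cell-state Micro-C + GWAS +
RNA-seq integration at desk scale, with every downstream quantity planted
and recorded in a truth manifest. Default study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 8 chromosomes × 12 Mb | enough territory for all features at < 60% occupancy |
| anchor resolutions | 1, 4, 16 kb | the three loop-call scales of multi-resolution callers |
| loops per cell type | 300 | hundreds of loops, seconds to generate |
| shared / single-anchor fractions | 0.20 / 0.10 | most loops differ between states, as observed for differentiation pairs |
| sentinels (study trait) | 40, each with 10 proxies | ~11 candidates per signal, matching the ~117 835 / 10 810 candidate-to-sentinel ratio |
| LD r² bounds | uniform on [0.3, 1.0] | straddles the 0.6 threshold so the strict filter is always exercised |
| proxy window | ±100 kb | typical LD-block scale |
| sentinels inside A anchors | 15% | yields an in-contact candidate fraction of the order of the published ~11% |
| control trait | 40 sentinels, 2% in-anchor | a trait unrelated to the biology, for the Fisher comparison |
| clustered sentinels | 50% | tight clouds (200–450 bp spacing, r² ≥ 0.65) plant retainable clusters; spread clouds (> 5000 bp spacing) plant none |
| genes | 200, bodies 5–30 kb, strands uniform | gene-dense enough for promoter assignment |
| DEG fraction | 0.30, 5 DEG bodies planted over cluster spans | plants cluster–DEG overlaps |
| terms | 30, 3 planted enriched (≥ 80% foreground members) | null and alternative terms in one set |

Feature territory is allocated by seeded uniform placement with rejection, so
loops, variant clouds and gene bodies interleave along chromosomes while
staying pairwise disjoint with ≥ 12 kb spacers — tight proxy clouds can never
chain across features into spurious clusters. Planted class counts use
largest-remainder rounding, so requested fractions are realized exactly.
Every stage draws from `default_rng([seed, stage_tag])`; regeneration under
one seed is byte-identical, file by file.

Ground truth is derived at generation time by brute force — all-pairs
point-in-anchor checks for in-contact status, union-find closure over the
selected candidates for expected clusters — never by the pipeline's own
sweep/chaining code, so truth-recovery tests compare two independent routes.

What the generator does **not** emulate: contact matrices or reads (loops are
planted calls, not called from data), LD computed from genotypes (r² values
are assigned), overlapping or nested loops within one cell type, realistic
gene length/strand structure, and chromosome-scale heterogeneity. Passing
tests therefore demonstrate correctness of the set algebra, counting and
statistics on called inputs — not robustness to caller noise or LD-panel
error.

## Numerical choices and degenerate inputs

Exact tests come from `scipy.stats` (Fisher two-sided, hypergeometric
survival function, binomial CDF) and BH from `statsmodels`; tests verify them
against exhaustive enumeration (all 2×2 tables with fixed margins; full
combinatorial sums for N ≤ 25; the literal step-up definition). Empty loop
files, zero-chromosome configs, empty variant tables and zero-cell 2×2
tables all run to completion with zeroed counts; both-zero regional counts
and zero candidate totals are errors, as the corresponding statistics are
undefined. Report JSON is schema-versioned, sorted-key, and byte-identical
across reruns of one config; the config hash excludes only the output
directory.

## Problem sizes

Module tests run on 4 × 6 Mb genomes with 60 loops per cell and 12 sentinels
per trait; oracle-equivalence suites use 100 random instances per operation
with up to ~1000 entities; truth-recovery runs 20 seeds. The full default
study (8 × 12 Mb, 300 loops) generates in about a second — sizes chosen so
the planted structure is non-trivial while the whole suite stays fast.

## Known limitations

* Loop matching is interval algebra on calls; two adjacent-but-distinct
  loops at coarse resolution can match under slack that would separate them
  at fine resolution.
* The regional count test assumes exchangeable loop calls between cell
  types; depth or callability differences between libraries violate that
  null.
* The enrichment universe (loop-assigned genes of either cell type) makes
  significance relative to loop-gene space, not the whole genome; with few
  assigned genes the test is weak by construction.
* One gene per loop (nearest promoter to either anchor) discards genuinely
  bivalent enhancer–promoter loops whose two anchors regulate different
  genes.
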