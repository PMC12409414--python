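# loopdiff

Differential chromatin-loop topology and GWAS-variant concordance analysis.

## The problem

Micro-C and Hi-C experiments call chromatin loops — pairs of genomic anchors
("contact regions") in frequent spatial contact — separately for two cell
states, for example precursor cells and a differentiated cell type such as
osteoclasts. Comparing the two call sets asks which loops are shared, which
keep one anchor while the other end moves, and which are unique to one cell
type (differential loop loci, DLLs). Candidate regulatory variants from GWAS
(lead/sentinel SNPs plus their linkage-disequilibrium proxies) can then be
intersected with loop contact regions to ask which putative causal variants
sit inside cell-type-specific chromatin contacts, how they cluster
positionally, how those clusters relate to differentially expressed genes
(DEGs), and which gene sets the loop-anchored genes over-represent.

`loopdiff` implements that integration pipeline for anyone with loop calls
(BEDPE), a variant table, gene/DEG tables and GMT gene sets — plus a
synthetic-data generator that plants every quantity of interest with recorded
ground truth, so the whole pipeline is testable end to end without any
restricted-access data.

## What it computes

* **Loop classification** — a loop in set A is `shared_loop` if some loop in
  set B matches at both anchors (anchor match = ≥ 1 bp interval overlap,
  optionally widened by `slack_bins` bins), `shared_single_anchor` if exactly
  one anchor matches, otherwise `unique` (the DLL class).
* **Candidate selection** — sentinels with association p < 1 × 10⁻⁵ (strict)
  and proxies with r² > 0.6 (strict) whose sentinel survives.
* **Variant-to-contact mapping** — sweep-line point-in-interval join in
  0-based half-open coordinates; "unique SNPs within unique contacts"
  counting; the percentage of candidates inside contacts.
* **Regional loop-count test** — exact binomial (p = 0.5, doubled smaller
  tail) for "a CL observed in A vs B" counts in a locus; Fisher's exact test
  for trait-vs-control contact enrichment.
* **SNP clustering** — merge-style chaining of candidates within 5000 bp,
  clusters with fewer than 10 SNPs discarded; inclusive first-to-last span.
* **Concordance windows** — unique SNPs/DEGs within {0, ±50 kb, ±200 kb,
  ±1 Mb} of each other and of DLL contacts.
* **Loop-anchored enrichment** — each loop assigned the gene with the closest
  promoter (TSS ± 1 kb, strand-aware), then hypergeometric upper-tail term
  tests with Benjamini–Hochberg correction, p_adj ≤ 0.05 significant.

## Worked example

```python
from loopdiff import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(outdir="out", seed=1, synthetic=SyntheticConfig(seed=1))
report = run_pipeline(cfg)
print(report["dll"]["class_counts_a"])
print(report["snp_mapping"]["unique_snps_in_contacts"],
      report["snp_mapping"]["candidate_count"],
      round(report["snp_mapping"]["fraction_in_contacts_pct"], 2))
print(report["clusters"]["cluster_count"],
      report["clusters"]["clusters_overlapping_deg"])
```

prints

```
{'shared_loop': 60, 'shared_single_anchor': 30, 'unique': 210}
55 358 15.36
20 5
```

With the default synthetic study (300 loops per cell type, 20% fully shared,
10% single-anchor-shared), loop classification recovers the planted 60/30/210
split exactly. Of 358 selected candidate variants, 55 fall inside a loop
contact of cell type A (15.36%); 20 SNP clusters survive the 5000 bp / ≥ 10
SNP rule and 5 of them overlap a planted DEG body. The full report (JSON plus
stage TSV/BED tables) lands in `out/`.

The same stages are available from the shell:

```bash
loopdiff synth --out data --seed 1
loopdiff classify-loops --a data/loops_A.bedpe --b data/loops_B.bedpe --out dll.tsv
loopdiff pipeline --config config.yaml
```

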