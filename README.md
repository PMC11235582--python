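# trconverge

Analysis of **convergent binding by multiple transcriptional regulators
(TRs)** from ChIP-seq peak calls. Several neurodevelopmental-disorder genes
encode TRs; when their ChIP-seq peaks in the same tissue are laid side by
side, the central questions are: do they bind the *same* loci, do those
loci sit in open chromatin, which genes do they converge on, and is that
convergence more than expected by chance given peak sizes and gene
covariates? `trconverge` implements that analysis as a reusable, tested
library:

- **Promoter annotation** — strand-aware promoter windows (the `w` = 2,000 bp
  immediately upstream of each TSS, unioned over a gene's TSSs); every peak
  is *proximal* (≥ 1 bp promoter overlap, crediting all overlapped genes) or
  *distal* (assigned to the nearest TSS).
- **Independent loci & co-binding classes** — peaks of the same class merge
  transitively (single-linkage, ≥ 1 bp) into loci; each locus carries its TR
  membership set, an ATAC (open-chromatin) flag and optional histone flags.
  A locus bound by all five TRs with ATAC is a **5TRa** locus; requiring a
  given trio plus ATAC gives **≥3TRa**.
- **Rank concordance** — per-assay top-*N* peak lists ordered by peak-caller
  p-value; for each pair, the co-location percentage and Spearman's ρ of the
  matched rank lists; panels compared by two-sided Wilcoxon rank-sum.
- **Enrichment statistics** — a length-preserving per-chromosome interval
  **shuffle null** (observed overlap count vs. uniform random re-placement,
  empirical *p* = (1 + #{null ≥ obs}) / (1 + n_perm)); a **covariate-matched
  gene-set permutation** (null sets drawn within cDNA-length decile bins);
  Pearson χ² (no continuity correction) and two-sided Fisher exact tests;
  BH-FDR / Bonferroni correction; expression stratification by bound-TR
  count with a logistic model of robust expression (log₂(TPM+1) ≥ 1);
  DEX filtering (|FC| ≥ 2, adjusted p ≤ 0.05); ΔΔCt fold changes
  (2^(−ΔΔCt)); VISTA-style per-tissue enhancer enrichment.
- **Synthetic data** — a generator that plants co-binding "hub" promoters,
  coupled peak rankings, expression effects and covariate confounds with a
  machine-readable truth ledger, so every stage is validated end to end
  without external downloads.

## Worked example

`examples/02_cobinding_loci.py` simulates 300 genes on a toy genome with a
planted hub fraction of 0.3, runs annotation and locus merging, and prints:

```
proximal loci by number of bound TRs (UpSet marginals):
  1 TRs:  123 loci (49.0%)
  2 TRs:   28 loci (11.2%)
  3 TRs:    9 loci (3.6%)
  4 TRs:    2 loci (0.8%)
  5 TRs:   89 loci (35.5%)
5TR proximal loci: 89, of which 88 (98.9%) have concurrent ATAC (5TRa)
genes with a proximal 5TRa locus: 88/300 (planted hub fraction 0.3)
5TR loci with max conservation > 0.5: 100.0%
```

Read: of the merged proximal loci, 89 are bound by all five TRs and nearly
all of those sit in open chromatin — the 5TRa signature — and the pipeline
recovers the planted 30% hub fraction (88/300 = 29.3%). The other examples
cover annotation (`01`), rank concordance with coupled vs. independent
rankings (`03`), and the permutation/contingency statistics (`04`).

A thin CLI wraps the same stages for shell use:

```bash
trconverge simulate --seed 9 --out sim/
trconverge converge --genes sim/genes.tsv --peaks sim/ARID1B.narrowPeak \
    ... --atac sim/ATAC.narrowPeak --out conv/
trconverge enrich --loci conv/loci.tsv --genes sim/genes.tsv \
    --gene-set sim/gene_set.tsv --out enr/
```

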