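# Methods

## Coordinate and interval conventions

All coordinates are 0-based half-open (BED convention); 1-based inputs must
be converted at the boundary. Chromosome names are compared by exact string
match — no "chr" aliasing — so namespace mixups fail loudly instead of
producing silently empty overlaps. Overlap means ≥ 1 shared base; bookended
intervals (end == next start) do **not** overlap and are never merged,
matching the strict half-open reading used by standard interval tooling.
narrowPeak column 8 carries −log10 p; the caller's −1 sentinel ("not
computed") maps to a missing score, which excludes the peak from rank-based
operations only — it still participates in all overlap computation.

## Promoter annotation

A promoter window is the `window_bp` (default 2,000) bases immediately 5′
of a TSS, excluding the TSS base itself: `[t − w, t)` on the + strand,
`[t + 1, t + 1 + w)` on the −. The exclusive-of-TSS reading is chosen
deliberately: it is the unique window that is simultaneously "the 2,000 bp
upstream" and "does not contain transcribed sequence" for a single-TSS
gene. Genes with several TSSs contribute the union of their windows
(merged per gene, not genome-wide, so different genes' promoters may
overlap). Windows are clipped to chromosome bounds.

A peak with ≥ 1 bp of overlap with any promoter window is *proximal* and
credits **all** overlapped genes; everything else is *distal*. Distal peaks
take the nearest TSS over all transcripts of all biotypes, strand-agnostic
(the source data do not distinguish upstream from downstream regulation at
distance). Distance from a peak `[s, e)` to a TSS `t` is 0 when `s ≤ t < e`
and otherwise `min(|t − s|, |t − (e − 1)|)` — edge-to-TSS using the last
covered base. Ties break by smaller distance, then lexicographically
smaller gene id, making annotation a deterministic total function. Peaks on
chromosomes absent from the gene table are distal with no gene and flagged.

## Independent loci and co-binding membership

Within each class (proximal/distal), TR peaks from all assays merge by
single linkage: transitively chained ≥ 1 bp overlaps become one *independent
locus*. Locus membership is the set of TR assays overlapping the merged
span; the ATAC flag (and any histone flags) are computed by overlap against
the locus but do not extend it — open-chromatin data classify loci, they do
not define them. `tr_count = |membership|`; a locus with all five TRs and
ATAC is 5TRa. Merging is computed with sorted-array sweeps and is verified
in the test suite against an exhaustive per-base connected-components
oracle on random small genomes.

Conservation is summarised per locus as the maximum track value over
overlapping score intervals, 0 where the track has no coverage (bases
absent from a conservation track are unalignable, hence unconserved), with
the reported fraction exceeding a threshold (default 0.5).

Distal-locus-to-gene linking: a gene is linked at window `w` when any
distal locus whose membership contains the required assays (default the
ARID1B/BCL11A/TBR1 trio with ATAC, `min_tr_count = 3`) lies within `w` bp
(edge-to-TSS, overlap = 0) of any TSS. Windows default to 100 kb and
500 kb; linked sets are monotone non-decreasing in `w` by construction.

## Rank concordance

Peak lists are ordered by descending −log10 p with ties broken by
(chrom, start, end), truncated to a fixed top *N* (defaults 10,000 proximal,
8,000 distal) so that peak count is not a variable; requesting more peaks
than exist is an error rather than a silent truncation. Each top-*N* peak
of list A is matched to the best-overlapping top-*N* peak of B (largest bp
overlap, ties toward the better B rank; many-to-one allowed, so the
intersection percentage is a per-query quantity ≤ 100). Spearman's ρ is
computed on the matched within-top-*N* rank pairs (average-rank handling of
ties); it needs ≥ 2 matched pairs and is reported absent otherwise. ρ is
computed once per unordered pair (lower label as query), making the panel
matrix symmetric by construction; intersection is reported directionally.
Panels are compared by a two-sided Wilcoxon rank-sum (Mann-Whitney) on
their collections of pairwise statistics — unpaired, since panels have
different sizes — exact when the pooled sample is ≤ 25 without ties,
otherwise the normal approximation with tie correction and no continuity
correction; a fully tied pooled sample reports p = 1.

## Permutation nulls

**Interval shuffle.** The statistic is the number of query loci with ≥ 1 bp
overlap of the merged target. Under the null each query locus is re-placed
uniformly at random on its own chromosome with its length preserved;
placements are independent, and shuffled loci may overlap one another.
This conditions on the size spectrum of the query set (the stated purpose
of the permutation), not on spacing or exclusion masks; masking support is
deliberately off by default. Placement is vectorised (all permutations
drawn as one matrix), so 999 permutations of a few hundred loci cost
milliseconds.

**Covariate-matched gene-set permutation.** The statistic is the number of
gene-set members whose indicator (e.g. "has a proximal 5TRa locus") is
true. Null sets are drawn without replacement within covariate quantile
bins (default deciles of cDNA length), matching the observed set's bin
occupancy, which removes confounding of set membership by the covariate.
`n_bins = 1` or a missing covariate gives the unmatched test. The
motivating confound is demonstrated, not assumed: with gene-set membership
and binding both tilted toward long genes and *no* direct coupling, the
unmatched test rejects far above α while the matched test stays calibrated.

Both tests report the add-one empirical p, `p = (1 + #extreme)/(1 + n_perm)`,
never 0, exact under exchangeability, and bit-reproducible given a seed.
With a discrete count statistic ties against the observed value are counted
as extreme, so the tests are conservative by up to the tie mass at the
rejection boundary; calibration fixtures therefore use configurations whose
expected overlap counts are in the tens, where the granularity of the
statistic is fine enough for rejection rates at α = 0.05 to be meaningful.

## Contingency and downstream statistics

χ² on a 2×2 is Pearson's statistic without continuity correction,
equivalently `N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))`, df = 1; a zero row or
column margin reports χ² as absent. The odds ratio is `ad/bc`, with the
Haldane-Anscombe +0.5 adjustment applied (and flagged) only when a cell is
zero; Fisher and χ² always use raw counts. Fisher's exact p is two-sided by
hypergeometric enumeration (verified against exhaustive enumeration for
N ≤ 50). Multiple testing uses Bonferroni or BH-FDR; Bonferroni ≥ BH ≥ raw
always, capped at 1.

DEX filtering is inclusive at both thresholds (|FC| ≥ 2 i.e. |log2FC| ≥ 1,
adjusted p ≤ 0.05), reading "greater or less than 2" as the standard
absolute-fold-change criterion. Expression stratification groups genes by
(proximal TR count, ATAC, distal linkage), reporting n, median, quartiles
and the robustly-expressed fraction (log₂(TPM+1) ≥ 1), plus a standard
maximum-likelihood logistic fit of robustness on stratum indicators
(coefficients with Wald p; omitted when the design is degenerate, e.g.
perfect separation). VISTA-style tissue enrichment excludes tissues with
fewer than 50 positive elements, tests each retained tissue with a
two-sided Fisher on (overlaps qualifying locus × positive in tissue), and
BH-corrects across tissues. ΔΔCt combines multiple housekeeping genes by
arithmetic mean of Ct; relative expression is 2^(−ΔΔCt).

## Synthetic data generator

The generator emulates the statistical structure the pipeline is meant to
detect, with every effect planted explicitly and recorded in a truth
ledger:

- **Genome/genes** — `n_chroms` × `chrom_length` (default 4 × 5 Mb),
  `n_genes` (default 1,000) evenly spaced TSSs with jitter, random strand,
  ~40% of genes with a second TSS, log-normal cDNA lengths (median 2 kb),
  85% protein-coding.
- **Hubs** — a fraction `hub_fraction` (default 0.3) of genes is chosen as
  co-binding hubs: all five TRs plus ATAC peak there. Peaks are centred on
  the promoter midpoint with uniform ±500 bp jitter; lengths are log-normal
  with median 800 bp (sdlog 0.4), consistent with merged co-binding loci of
  ~2 kb. Non-hub binding is independent per TR at `independent_rate`
  (default 0.08), optionally tilted by `binding_length_bias` along
  standardized log cDNA length; ATAC appears at non-hub promoters at
  `atac_background_rate` (0.15).
- **Peak scores** — each hub has a latent quality u ~ U(0,1); a TR's
  −log10 p at that hub blends the latent with independent noise via
  `pvalue_rank_coupling` (default 0.7), giving a tunable target for
  cross-TR rank concordance. Background peaks score independently.
- **Distal structure** — `n_distal_hubs` co-bound intergenic sites
  (ARID1B/BCL11A/TBR1 trio + ATAC, all five TRs with probability 0.3) and
  per-TR background peaks.
- **Expression** — log₂(TPM+1) = β₀ + β₁·(bound TR count) + β₂·ATAC +
  N(0, σ), floored at 0 (defaults 0.3, 0.7, 0.8, σ = 1).
- **Gene set / DGE** — a gene set (default size 102) sampled with weights
  exp(hub_bias·is_hub + length_bias·z_len); a DGE table with planted up and
  down genes whose effects clear the DEX thresholds by construction while
  null genes cannot.
- **Conservation** — hub promoters score U(0.55, 1), background promoters
  U(0, 0.45), so the conserved fraction of recovered hub loci is a known
  quantity.

`null_dataset` zeroes every coupling (no hubs, no rank coupling,
β₁ = β₂ = 0, no hub bias in the gene set) while retaining any length
biases, so each test's null holds by construction. Identical seeds give
byte-identical files.

**What the generator does not emulate:** read-level noise, peak-calling
artefacts, sequence/motif content, chromosome-scale covariates (GC,
replication timing), and realistic inter-gene spacing heterogeneity.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not robustness to every
property of real ChIP-seq data.

## Problem sizes and determinism

Calibration suites use 500 replicate null datasets at 999 permutations;
interval-oracle equivalence uses 200 random genomes of ≤ 10 kb; recovery
uses 1,000 genes; the concordance contrast uses 100 seeds of a 150-gene
panel. All randomness flows through `numpy.random.default_rng` seeded
explicitly; every permutation result records its seed, and rerunning any
stage with the same inputs and seed reproduces outputs exactly.

## Known limitations

- The nearest-TSS search is strand-agnostic; a strand-aware variant would
  require a modelling choice the source framework does not make.
- `genes_with_proximal_signature` scans per gene window; it is linear in
  genes × loci per chromosome and fine at the scales used here, but not
  tuned for whole-genome catalogs of millions of loci.
- The logistic stratification model treats TR count as categorical
  indicators; with sparse high-count strata the fit may be omitted rather
  than regularised.
- Cross-dataset locus matching assumes coordinates already share a space;
  no coordinate lift-over is provided.
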