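"""Simulate a small co-binding landscape and classify peaks around promoters.

Generates five TR ChIP-seq peak sets plus ATAC-seq on a toy genome in which
30% of promoters are co-binding hubs, then labels every peak proximal
(overlapping the 2 kb window upstream of a TSS) or distal.
"""

from trconverge import SyntheticConfig, build_promoters, classify_peaks, generate_dataset

cfg = SyntheticConfig(seed=7, n_genes=300, n_chroms=2, chrom_length=1_800_000,
                      geneset_size=50)
bundle = generate_dataset(cfg)
promoters = build_promoters(bundle.genes, cfg.promoter_window, bundle.genome)

print(f"genome: {cfg.n_chroms} chromosomes x {cfg.chrom_length:,} bp, "
      f"{cfg.n_genes} genes, {len(bundle.truth['hub_genes'])} planted hubs")
for label, peaks in bundle.tr_peaks.items():
    ann = classify_peaks(peaks, promoters, bundle.genes)
    print(f"{label:8s} {len(peaks):4d} peaks -> {ann.n_proximal:4d} proximal, "
          f"{ann.n_distal:4d} distal")
print("Proximal = >=1 bp overlap with a promoter window (2,000 bp upstream of")
print("any TSS of a gene); distal peaks are assigned to their nearest TSS.")
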