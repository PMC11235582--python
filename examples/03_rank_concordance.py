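"""Rank concordance of top-N peak lists: shared vs independent binding.

Each TR's peaks are ranked by peak-caller p-value and truncated to a fixed
top N; for every TR pair we report the fraction of co-located peaks and the
Spearman rho of their matched rank lists. Panels generated with coupled
peak quality at hubs show high rho; uncoupled panels hover near zero —
the signature distinguishing a convergent regulatory panel from unrelated
factors.
"""

from trconverge import (
    PeakSet,
    SyntheticConfig,
    build_promoters,
    classify_peaks,
    compare_panels,
    generate_dataset,
    panel_concordance,
)


def proximal_panel(coupling: float, seed: int = 3):
    cfg = SyntheticConfig(seed=seed, n_genes=200, n_chroms=2,
                          chrom_length=1_400_000, geneset_size=40,
                          hub_fraction=0.5, pvalue_rank_coupling=coupling,
                          n_distal_hubs=0, distal_background_per_tr=25)
    b = generate_dataset(cfg)
    promoters = build_promoters(b.genes, cfg.promoter_window, b.genome)
    sets = []
    for lab, ps in b.tr_peaks.items():
        ann = classify_peaks(ps, promoters, b.genes)
        sub = ps.df[ann.table["peak_class"].to_numpy() == "proximal"]
        sets.append(PeakSet(lab, sub.dropna(subset=["score_neglog10p"]),
                            cfg.genome_label))
    n = min(len(s) for s in sets)
    return panel_concordance(sets, n=n)


coupled = proximal_panel(coupling=0.7)
uncoupled = proximal_panel(coupling=0.0)
print(f"coupled panel:   mean rho {coupled['rho'].mean():+.3f}, "
      f"mean intersection {coupled['intersect_pct_ab'].mean():.1f}%")
print(f"uncoupled panel: mean rho {uncoupled['rho'].mean():+.3f}, "
      f"mean intersection {uncoupled['intersect_pct_ab'].mean():.1f}%")

cmp = compare_panels(coupled, uncoupled, statistic="rho")
print(f"two-sided Wilcoxon rank-sum on the 10+10 pairwise rho values: "
      f"p = {cmp.wilcoxon_p:.2e} ({cmp.method})")
print("A significant difference says the coupled TRs rank their shared")
print("binding sites concordantly — evidence of convergent regulation.")
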