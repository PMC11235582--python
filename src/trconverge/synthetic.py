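"""Synthetic regulatory-genomics fixtures with known ground truth.

The generator emulates the statistical structure of a multi-TR ChIP-seq
study of co-binding: a fraction of promoters are "hubs" where all five TRs
and ATAC co-bind; remaining binding is independent per TR; peak -log10
p-values at hubs share a latent rank (tunable coupling) so cross-TR rank
concordance has a known direction; expression increases with the number of
proximally bound TRs; and a gene set can be confounded with cDNA length.
Every coupling can be zeroed to obtain exact null fixtures for calibrating
the permutation tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    GeneModel,
    GenomeDef,
    PeakSet,
    ScoreTrack,
    write_gene_table,
    write_narrowpeak,
    write_score_track,
)

__all__ = ["SyntheticConfig", "FixtureBundle", "generate_dataset", "null_dataset",
           "write_dataset", "DEFAULT_TR_LABELS"]

DEFAULT_TR_LABELS = ("ARID1B", "BCL11A", "FOXP1", "TBR1", "TCF7L2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults define the study-like conditions.

    ``hub_fraction`` is the fraction of genes whose promoter is a five-TR +
    ATAC co-binding hub. ``pvalue_rank_coupling`` in [0,1] blends a shared
    latent peak quality into each TR's -log10 p at hubs (1 = identical
    ranking, 0 = independent). ``binding_length_bias`` tilts the per-TR
    independent binding probability with standardized log cDNA length, and
    ``geneset_length_bias`` tilts gene-set sampling the same way — together
    they recreate the confound that motivates covariate-matched permutation.
    Expression follows log2(TPM+1) = b0 + b1*(TR count) + b2*ATAC + noise,
    floored at 0.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 1_000
    extra_tss_rate: float = 0.4
    promoter_window: int = 2_000
    hub_fraction: float = 0.3
    independent_rate: float = 0.08
    atac_background_rate: float = 0.15
    peak_length_meanlog: float = 6.685  # log(800) — median peak ~800 bp
    peak_length_sdlog: float = 0.4
    peak_jitter_bp: int = 500
    pvalue_rank_coupling: float = 0.7
    n_distal_hubs: int = 60
    distal_background_per_tr: int = 150
    expression_beta0: float = 0.3
    expression_beta1: float = 0.7
    expression_beta2: float = 0.8
    expression_sigma: float = 1.0
    geneset_size: int = 102
    geneset_hub_bias: float = 2.0
    geneset_length_bias: float = 0.0
    binding_length_bias: float = 0.0
    dge_n_up: int = 7
    dge_n_down: int = 5
    dge_effect_log2fc: float = 2.0
    genome_label: str = "synth1"
    tr_labels: tuple[str, ...] = DEFAULT_TR_LABELS

    def validate(self) -> None:
        for name in ("hub_fraction", "independent_rate", "atac_background_rate",
                     "pvalue_rank_coupling", "extra_tss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0 or self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("n_genes, n_chroms, chrom_length must be positive")
        if self.geneset_size > self.n_genes:
            raise ValueError("geneset_size exceeds n_genes")
        if self.dge_n_up + self.dge_n_down > self.n_genes:
            raise ValueError("more planted DEX genes than genes")
        if self.expression_beta1 < 0:
            raise ValueError("expression_beta1 must be >= 0 in presets")


@dataclass
class FixtureBundle:
    """In-memory fixture: inputs for every pipeline stage plus the truth."""

    config: SyntheticConfig
    genome: GenomeDef
    genes: list[GeneModel]
    tr_peaks: dict[str, PeakSet]
    atac_peaks: PeakSet
    conservation: ScoreTrack
    expression: pd.Series  # gene_id -> log2(TPM+1)
    gene_set: set[str]
    dge_table: pd.DataFrame
    truth: dict


def _peak_lengths(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    ln = rng.lognormal(cfg.peak_length_meanlog, cfg.peak_length_sdlog, size=n)
    return np.maximum(ln.astype(np.int64), 50)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(config: SyntheticConfig) -> FixtureBundle:
    """Generate a full fixture bundle, reproducible from ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome = GenomeDef({c: cfg.chrom_length for c in chroms})

    # --- gene models: evenly spaced TSSs with jitter, random strand -------
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    margin = max(cfg.promoter_window + 1_000, 5_000)
    genes: list[GeneModel] = []
    log_len = rng.normal(np.log(2_000.0), 0.8, size=cfg.n_genes)
    cdna = np.maximum(np.exp(log_len).astype(np.int64), 100)
    gi = 0
    for ci, chrom in enumerate(chroms):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        spacing = (cfg.chrom_length - 2 * margin) / k
        if spacing < 2 * cfg.promoter_window:
            raise ValueError("genome too small for the requested gene density")
        for j in range(k):
            tss = int(margin + j * spacing + rng.integers(0, max(int(spacing) // 4, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            tss_list = [tss]
            if rng.random() < cfg.extra_tss_rate:
                # secondary TSS a short way along the same promoter
                tss_list.append(tss + int(rng.integers(50, 400)) * (1 if strand == "+" else -1))
            biotype = "protein_coding" if rng.random() < 0.85 else "non_coding"
            genes.append(GeneModel(
                gene_id=f"G{gi:05d}", chrom=chrom, strand=strand,
                tss_list=sorted(tss_list), cdna_length=int(cdna[gi]),
                biotype=biotype,
            ))
            gi += 1

    gene_ids = np.array([g.gene_id for g in genes])
    z_len = (log_len - log_len.mean()) / max(log_len.std(), 1e-9)

    # --- hub assignment and per-TR binding indicators ---------------------
    n_hub = int(round(cfg.hub_fraction * cfg.n_genes))
    hub_idx = rng.choice(cfg.n_genes, size=n_hub, replace=False) if n_hub else np.empty(0, np.int64)
    is_hub = np.zeros(cfg.n_genes, dtype=bool)
    is_hub[hub_idx] = True

    base_logit = np.log(cfg.independent_rate / (1 - cfg.independent_rate)) if cfg.independent_rate > 0 else -np.inf
    p_bind = (
        _sigmoid(base_logit + cfg.binding_length_bias * z_len)
        if np.isfinite(base_logit)
        else np.zeros(cfg.n_genes)
    )
    bound = {}  # label -> bool per gene (proximal binding)
    for label in cfg.tr_labels:
        bound[label] = is_hub | (rng.random(cfg.n_genes) < p_bind)
    atac_at_gene = is_hub | (rng.random(cfg.n_genes) < cfg.atac_background_rate)

    # --- proximal peaks ----------------------------------------------------
    hub_latent = rng.random(cfg.n_genes)  # shared peak-quality rank at hubs

    def promoter_midpoint(g: GeneModel) -> int:
        t = g.tss_list[0]
        if g.strand == "+":
            return t - cfg.promoter_window // 2
        return t + 1 + cfg.promoter_window // 2

    tr_rows: dict[str, list] = {label: [] for label in cfg.tr_labels}
    atac_rows: list = []
    for idx, g in enumerate(genes):
        mid = promoter_midpoint(g)
        for label in cfg.tr_labels:
            if not bound[label][idx]:
                continue
            L = int(_peak_lengths(rng, 1, cfg)[0])
            center = mid + int(rng.integers(-cfg.peak_jitter_bp, cfg.peak_jitter_bp + 1))
            s = max(center - L // 2, 0)
            e = min(s + L, cfg.chrom_length)
            if is_hub[idx]:
                latent = (cfg.pvalue_rank_coupling * hub_latent[idx]
                          + (1 - cfg.pvalue_rank_coupling) * rng.random())
            else:
                latent = rng.random()
            score = 2.0 + 8.0 * latent + rng.random() * 1e-6  # tie-free
            tr_rows[label].append((g.chrom, s, e, None, ".", score))
        if atac_at_gene[idx]:
            L = int(_peak_lengths(rng, 1, cfg)[0]) + 200  # ATAC peaks run wider
            center = mid + int(rng.integers(-cfg.peak_jitter_bp, cfg.peak_jitter_bp + 1))
            s = max(center - L // 2, 0)
            atac_rows.append((g.chrom, s, min(s + L, cfg.chrom_length), None, ".", np.nan))

    # --- distal peaks: co-bound distal hubs + per-TR background -----------
    # the co-bound distal trio mirrors the default link requirement
    trio = (cfg.tr_labels[0], cfg.tr_labels[1], cfg.tr_labels[3])  # ARID1B, BCL11A, TBR1
    distal_hubs: list[tuple[str, int]] = []
    prom_guard = cfg.promoter_window + 3_000
    tss_by_chrom = {c: np.array(sorted(t for g in genes if g.chrom == c for t in g.tss_list))
                    for c in chroms}
    for _ in range(cfg.n_distal_hubs):
        chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
        for _attempt in range(50):
            pos = int(rng.integers(margin, cfg.chrom_length - margin))
            tss = tss_by_chrom[chrom]
            if tss.size == 0 or np.abs(tss - pos).min() > prom_guard:
                break
        distal_hubs.append((chrom, pos))
        members = cfg.tr_labels if rng.random() < 0.3 else trio
        for label in members:
            L = int(_peak_lengths(rng, 1, cfg)[0])
            c = pos + int(rng.integers(-cfg.peak_jitter_bp, cfg.peak_jitter_bp + 1))
            s = max(c - L // 2, 0)
            score = 2.0 + 8.0 * rng.random()
            tr_rows[label].append((chrom, s, min(s + L, cfg.chrom_length), None, ".", score))
        L = int(_peak_lengths(rng, 1, cfg)[0]) + 200
        s = max(pos - L // 2, 0)
        atac_rows.append((chrom, s, min(s + L, cfg.chrom_length), None, ".", np.nan))
    for label in cfg.tr_labels:
        for _ in range(cfg.distal_background_per_tr):
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            pos = int(rng.integers(margin, cfg.chrom_length - margin))
            L = int(_peak_lengths(rng, 1, cfg)[0])
            s = max(pos - L // 2, 0)
            score = 2.0 + 8.0 * rng.random()
            tr_rows[label].append((chrom, s, min(s + L, cfg.chrom_length), None, ".", score))

    columns = ["chrom", "start", "end", "name", "strand", "score_neglog10p"]
    tr_peaks = {
        label: PeakSet(label, pd.DataFrame(rows, columns=columns), cfg.genome_label)
        for label, rows in tr_rows.items()
    }
    atac_peaks = PeakSet("ATAC", pd.DataFrame(atac_rows, columns=columns), cfg.genome_label)

    # --- conservation: hub promoters conserved, background not ------------
    cons_rows = []
    for idx, g in enumerate(genes):
        t = g.tss_list[0]
        s = max(t - cfg.promoter_window, 0) if g.strand == "+" else t + 1
        e = s + cfg.promoter_window
        v = rng.uniform(0.55, 1.0) if is_hub[idx] else rng.uniform(0.0, 0.45)
        cons_rows.append((g.chrom, s, min(e, cfg.chrom_length), round(float(v), 6)))
    cons = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "value"])
    # keep per-chromosome intervals disjoint (drop later overlappers)
    keep = []
    for chrom, sub in cons.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        last_end = -1
        for i, row in sub.iterrows():
            if row["start"] >= last_end:
                keep.append(i)
                last_end = row["end"]
    conservation = ScoreTrack(cons.loc[sorted(keep)].reset_index(drop=True))

    # --- expression --------------------------------------------------------
    tr_count_true = np.sum([bound[label] for label in cfg.tr_labels], axis=0)
    noise = rng.normal(0.0, cfg.expression_sigma, size=cfg.n_genes)
    log2tpm = np.maximum(
        cfg.expression_beta0
        + cfg.expression_beta1 * tr_count_true
        + cfg.expression_beta2 * atac_at_gene.astype(float)
        + noise,
        0.0,
    )
    expression = pd.Series(log2tpm, index=gene_ids, name="log2_tpm1")

    # --- gene set (optionally hub- and length-biased) ----------------------
    w = np.exp(cfg.geneset_hub_bias * is_hub + cfg.geneset_length_bias * z_len)
    p = w / w.sum()
    set_idx = rng.choice(cfg.n_genes, size=cfg.geneset_size, replace=False, p=p)
    gene_set = set(gene_ids[set_idx].tolist())

    # --- DGE table with planted up/down genes ------------------------------
    perm = rng.permutation(cfg.n_genes)
    up_idx = perm[: cfg.dge_n_up]
    down_idx = perm[cfg.dge_n_up: cfg.dge_n_up + cfg.dge_n_down]
    lfc = rng.normal(0.0, 0.3, size=cfg.n_genes)
    padj = rng.uniform(0.051, 1.0, size=cfg.n_genes)
    lfc[up_idx] = cfg.dge_effect_log2fc + rng.normal(0, 0.2, size=up_idx.size)
    lfc[down_idx] = -cfg.dge_effect_log2fc + rng.normal(0, 0.2, size=down_idx.size)
    padj[up_idx] = rng.uniform(1e-8, 1e-3, size=up_idx.size)
    padj[down_idx] = rng.uniform(1e-8, 1e-3, size=down_idx.size)
    dge_table = pd.DataFrame({
        "gene": gene_ids, "log2fc": np.round(lfc, 6), "padj": np.round(padj, 10)
    })

    truth = {
        "hub_genes": sorted(gene_ids[is_hub].tolist()),
        "hub_fraction": cfg.hub_fraction,
        "distal_hubs": [{"chrom": c, "pos": int(p_)} for c, p_ in distal_hubs],
        "gene_set": sorted(gene_set),
        "dge_up": sorted(gene_ids[up_idx].tolist()),
        "dge_down": sorted(gene_ids[down_idx].tolist()),
        "tr_count_true": {str(g): int(n) for g, n in zip(gene_ids, tr_count_true)},
        "config": dataclasses.asdict(cfg),
    }
    return FixtureBundle(
        config=cfg, genome=genome, genes=genes, tr_peaks=tr_peaks,
        atac_peaks=atac_peaks, conservation=conservation, expression=expression,
        gene_set=gene_set, dge_table=dge_table, truth=truth,
    )


def null_dataset(config: SyntheticConfig) -> FixtureBundle:
    """Fixture with every planted coupling zeroed.

    No hubs, no shared p-value ranking, no expression effect of binding, and
    no gene-set bias beyond any configured length bias — so the null of each
    enrichment test holds by construction.
    """
    cfg = replace(
        config,
        hub_fraction=0.0,
        pvalue_rank_coupling=0.0,
        expression_beta1=0.0,
        expression_beta2=0.0,
        geneset_hub_bias=0.0,
        n_distal_hubs=0,
    )
    return generate_dataset(cfg)


def write_dataset(bundle: FixtureBundle, outdir: str | Path) -> dict[str, str]:
    """Write the bundle as standard-format text files; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for label, ps in bundle.tr_peaks.items():
        p = outdir / f"{label}.narrowPeak"
        write_narrowpeak(ps, p)
        paths[label] = str(p)
    write_narrowpeak(bundle.atac_peaks, outdir / "ATAC.narrowPeak")
    paths["ATAC"] = str(outdir / "ATAC.narrowPeak")
    write_gene_table(bundle.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    write_score_track(bundle.conservation, outdir / "conservation.bedgraph")
    paths["conservation"] = str(outdir / "conservation.bedgraph")
    expr = bundle.expression.rename_axis("gene_id").reset_index()
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False,
                float_format="%.6f")
    paths["expression"] = str(outdir / "expression.tsv")
    pd.DataFrame({"gene_id": sorted(bundle.gene_set)}).to_csv(
        outdir / "gene_set.tsv", sep="\t", index=False)
    paths["gene_set"] = str(outdir / "gene_set.tsv")
    bundle.dge_table.to_csv(outdir / "dge.tsv", sep="\t", index=False,
                            float_format="%.10g")
    paths["dge"] = str(outdir / "dge.tsv")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in bundle.genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = str(outdir / "chrom.sizes")
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(bundle.truth, fh, sort_keys=True)
    paths["truth"] = str(outdir / "truth.yaml")
    return paths
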