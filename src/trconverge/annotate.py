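"""Promoter construction and proximal/distal peak classification.

A promoter window is the ``window_bp`` bases immediately 5' (upstream) of a
transcription start site, excluding the TSS base itself: for a + strand TSS
``t`` the window is [t - window_bp, t); for a - strand TSS it is
[t + 1, t + 1 + window_bp). Genes with several TSSs contribute the union of
their windows. A peak overlapping any promoter window by >=1 bp is
"proximal" and credits every overlapped gene; all other peaks are "distal"
and are assigned to the nearest TSS across all genes on their chromosome,
strand-agnostically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .genome_io import GeneModel, GenomeDef, PeakSet

__all__ = [
    "PromoterMap",
    "AnnotationResult",
    "build_promoters",
    "classify_peaks",
    "genes_with_proximal_signature",
]

DEFAULT_PROMOTER_WINDOW = 2_000


@dataclass
class PromoterMap:
    """Per-gene merged promoter windows.

    ``windows`` maps gene_id -> dataframe (chrom, start, end); unions are per
    gene, so two genes' promoters may overlap each other.
    """

    windows: dict[str, pd.DataFrame]
    window_bp: int

    def total_length(self, gene_id: str) -> int:
        w = self.windows[gene_id]
        return int((w["end"] - w["start"]).sum())

    def as_frame(self) -> pd.DataFrame:
        frames = []
        for gene_id, w in self.windows.items():
            f = w.copy()
            f["gene_id"] = gene_id
            frames.append(f)
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class AnnotationResult:
    """Per-peak proximal/distal classification for one assay.

    ``table`` columns: peak_index, chrom, start, end, peak_class
    ({proximal, distal}), proximal_genes (comma-joined, proximal only),
    distal_gene (nearest-TSS gene, distal only), distance_bp, orphan
    (True when the peak's chromosome has no annotated gene).
    """

    assay_label: str
    table: pd.DataFrame

    @property
    def n_proximal(self) -> int:
        return int((self.table["peak_class"] == "proximal").sum())

    @property
    def n_distal(self) -> int:
        return int((self.table["peak_class"] == "distal").sum())

    def subset(self, peak_class: str) -> pd.DataFrame:
        return self.table[self.table["peak_class"] == peak_class]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_promoters(
    genes: Sequence[GeneModel],
    window_bp: int = DEFAULT_PROMOTER_WINDOW,
    genome: GenomeDef | None = None,
) -> PromoterMap:
    """Strand-aware promoter unions, clipped to chromosome bounds."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    windows: dict[str, pd.DataFrame] = {}
    for gene in genes:
        chrom_len = None
        if genome is not None:
            if gene.chrom not in genome.chrom_sizes:
                raise ValueError(f"gene {gene.gene_id}: chromosome {gene.chrom} not in genome")
            chrom_len = genome.chrom_sizes[gene.chrom]
        starts, ends = [], []
        for tss in gene.tss_list:
            if chrom_len is not None and not (0 <= tss < chrom_len):
                raise ValueError(
                    f"gene {gene.gene_id}: TSS {tss} outside chromosome {gene.chrom}"
                )
            if gene.strand == "+":
                s, e = tss - window_bp, tss
            else:
                s, e = tss + 1, tss + 1 + window_bp
            s = max(s, 0)
            if chrom_len is not None:
                e = min(e, chrom_len)
            if s < e:
                starts.append(s)
                ends.append(e)
        ms, me = iv.merge_intervals(np.array(starts, dtype=np.int64),
                                    np.array(ends, dtype=np.int64))
        windows[gene.gene_id] = pd.DataFrame(
            {"chrom": gene.chrom, "start": ms, "end": me}
        )
    return PromoterMap(windows=windows, window_bp=window_bp)


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: sorted TSS positions and parallel gene-id array.

    Ties at the same position are ordered by gene_id so the downstream
    lexicographic tie rule is deterministic.
    """
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        for tss in g.tss_list:
            per_chrom.setdefault(g.chrom, []).append((tss, g.gene_id))
    out = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([p[0] for p in pairs], dtype=np.int64),
            np.array([p[1] for p in pairs], dtype=object),
        )
    return out


def classify_peaks(
    peaks: PeakSet,
    promoters: PromoterMap,
    genes: Sequence[GeneModel],
) -> AnnotationResult:
    """Classify every peak as proximal (>=1 bp promoter overlap) or distal.

    Distal peaks get the nearest TSS over all transcripts; distance is the
    minimum over both peak edges (last covered base for the right edge),
    zero when the TSS falls inside the peak. Ties go to the smallest
    distance, then lexicographically smallest gene_id. Peaks on chromosomes
    absent from the gene table are distal with no gene and flagged orphan.
    """
    gene_lookup = {g.gene_id: g for g in genes}
    # flatten promoter windows into per-chromosome arrays with gene labels
    prom = promoters.as_frame()
    prom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in prom.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        prom_by_chrom[str(chrom)] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
            sub["gene_id"].to_numpy()[order],
        )
    tss_by_chrom = _tss_index(genes)

    records = []
    df = peaks.df
    for idx, row in enumerate(df.itertuples(index=False)):
        chrom, s, e = row.chrom, int(row.start), int(row.end)
        hit_genes: set[str] = set()
        if chrom in prom_by_chrom:
            ps, pe, pg = prom_by_chrom[chrom]
            # windows with start < e and end > s overlap the peak
            cand = (ps < e) & (pe > s)
            if cand.any():
                hit_genes = set(pg[cand])
        if hit_genes:
            records.append(
                (idx, chrom, s, e, "proximal", ",".join(sorted(hit_genes)),
                 None, 0, False)
            )
            continue
        if chrom not in tss_by_chrom:
            records.append((idx, chrom, s, e, "distal", None, None, -1, True))
            continue
        positions, gene_ids = tss_by_chrom[chrom]
        dist = np.where(
            (positions >= s) & (positions < e),
            0,
            np.minimum(np.abs(positions - s), np.abs(positions - (e - 1))),
        )
        best = int(dist.min())
        tied = np.flatnonzero(dist == best)
        gene = min(str(gene_ids[t]) for t in tied)
        records.append((idx, chrom, s, e, "distal", None, gene, best, False))

    table = pd.DataFrame(
        records,
        columns=["peak_index", "chrom", "start", "end", "peak_class",
                 "proximal_genes", "distal_gene", "distance_bp", "orphan"],
    )
    return AnnotationResult(assay_label=peaks.assay_label, table=table)


def genes_with_proximal_signature(
    locus_table,
    promoters: PromoterMap,
    min_tr_count: int = 5,
    require_atac: bool = True,
    gene_set: Iterable[str] | None = None,
) -> tuple[set[str], dict]:
    """Genes whose promoter overlaps a proximal locus with >= min_tr_count
    TRs (and an ATAC peak if required), plus a count/percentage summary for
    an optional gene set.

    Returns (qualifying_genes, summary). ``summary`` has keys n_qualifying,
    and when a gene set is supplied: set_size, n_in_set, pct_in_set.
    """
    loci = locus_table.df
    qual = loci[(loci["peak_class"] == "proximal") & (loci["tr_count"] >= min_tr_count)]
    if require_atac:
        qual = qual[qual["atac"]]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in qual.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
        )
    qualifying: set[str] = set()
    for gene_id, w in promoters.windows.items():
        if w.empty:
            continue
        chrom = str(w["chrom"].iloc[0])
        if chrom not in by_chrom:
            continue
        ls, le = by_chrom[chrom]
        ws = w["start"].to_numpy()
        we = w["end"].to_numpy()
        # any locus overlapping any window of this gene
        hit = False
        for s, e in zip(ws, we):
            if np.any((ls < e) & (le > s)):
                hit = True
                break
        if hit:
            qualifying.add(gene_id)
    summary: dict = {"n_qualifying": len(qualifying)}
    if gene_set is not None:
        gene_set = set(gene_set)
        if not gene_set:
            raise ValueError("gene_set is empty")
        n_in = len(qualifying & gene_set)
        summary.update(
            set_size=len(gene_set),
            n_in_set=n_in,
            pct_in_set=100.0 * n_in / len(gene_set),
        )
    return qualifying, summary
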