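"""Merging peaks across assays into independent loci and summarising them.

An "independent locus" is a maximal region formed by transitively merging
overlapping TR peaks of the same class (proximal or distal): single-linkage
with >=1 bp overlap, bookended peaks kept separate. Each locus records the
set of TR assays with >=1 bp overlap (its membership), whether any ATAC peak
overlaps it, and optional histone flags. A locus bound by all five TRs with
an ATAC peak is a "5TRa" locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .annotate import AnnotationResult
from .genome_io import GenomeDef, PeakSet, ScoreTrack

__all__ = [
    "LocusTable",
    "OverlapFractions",
    "ConservationSummary",
    "LinkConfig",
    "merge_loci",
    "membership_counts",
    "overlap_fractions",
    "conservation_summary",
    "link_distal_to_genes",
    "cross_dataset_locus_match",
    "proportion_pct",
]


def proportion_pct(numerator: int, denominator: int) -> float:
    """A percentage as reported: 100 * k / n."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


@dataclass
class LocusTable:
    """Merged independent loci with per-assay membership flags.

    ``df`` columns: chrom, start, end, peak_class, tr_count, atac, one
    boolean column per TR label, and one per histone label when provided.
    """

    df: pd.DataFrame
    tr_labels: list[str]
    histone_labels: list[str]
    genome_label: str = "unspecified"

    def __len__(self) -> int:
        return len(self.df)

    def membership(self, i: int) -> frozenset[str]:
        row = self.df.iloc[i]
        return frozenset(t for t in self.tr_labels if row[t])

    def subset(self, peak_class: str | None = None, min_tr_count: int = 0,
               require_atac: bool = False,
               required_assays: Iterable[str] = ()) -> pd.DataFrame:
        df = self.df
        if peak_class is not None:
            df = df[df["peak_class"] == peak_class]
        if min_tr_count:
            df = df[df["tr_count"] >= min_tr_count]
        if require_atac:
            df = df[df["atac"]]
        for assay in required_assays:
            df = df[df[assay]]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class OverlapFractions:
    peak_fraction: float        # % of query peaks with >=1 bp overlap
    nucleotide_fraction: float  # % of query-covered bp inside target


@dataclass
class ConservationSummary:
    per_locus_max: np.ndarray
    threshold: float
    fraction_above: float  # percent

    @property
    def n_above(self) -> int:
        return int((self.per_locus_max > self.threshold).sum())


@dataclass
class LinkConfig:
    """Configuration for distal-locus-to-gene window linking."""

    windows_bp: tuple[int, ...] = (100_000, 500_000)
    min_tr_count: int = 3
    required_assays: tuple[str, ...] = ("ARID1B", "BCL11A", "TBR1")
    require_atac: bool = True

    def __post_init__(self) -> None:
        if list(self.windows_bp) != sorted(self.windows_bp):
            raise ValueError("windows_bp must be sorted ascending")


def _class_of_peaks(annotation: AnnotationResult) -> pd.Series:
    return annotation.table.set_index("peak_index")["peak_class"]


def merge_loci(
    tr_peaksets: Sequence[PeakSet],
    atac_peakset: PeakSet | None,
    annotations: Mapping[str, AnnotationResult],
    histone_peaksets: Sequence[PeakSet] = (),
) -> LocusTable:
    """Merge TR peaks into independent loci, per class, with membership flags.

    ``annotations`` maps assay label -> AnnotationResult for every TR set
    (ATAC/histone sets only flag loci; they are not merged into them).
    """
    genomes = {ps.genome_label for ps in tr_peaksets}
    if atac_peakset is not None:
        genomes.add(atac_peakset.genome_label)
    for hp in histone_peaksets:
        genomes.add(hp.genome_label)
    if len(genomes) > 1:
        raise ValueError(f"mixed genome labels: {sorted(genomes)}")
    genome_label = next(iter(genomes)) if genomes else "unspecified"

    tr_labels = [ps.assay_label for ps in tr_peaksets]
    histone_labels = [ps.assay_label for ps in histone_peaksets]
    flag_sets = {ps.assay_label: ps.by_chrom() for ps in histone_peaksets}
    atac_by_chrom = atac_peakset.by_chrom() if atac_peakset is not None else {}

    rows = []
    for peak_class in ("proximal", "distal"):
        # gather this class's peaks from every TR set, tagged by assay
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for ps in tr_peaksets:
            if ps.assay_label not in annotations:
                raise ValueError(f"no annotation supplied for {ps.assay_label}")
            cls = _class_of_peaks(annotations[ps.assay_label])
            sub = ps.df[cls.reindex(range(len(ps.df))).to_numpy() == peak_class]
            for row in sub.itertuples(index=False):
                per_chrom.setdefault(row.chrom, []).append(
                    (int(row.start), int(row.end), ps.assay_label)
                )
        for chrom in sorted(per_chrom):
            entries = per_chrom[chrom]
            starts = np.array([t[0] for t in entries], dtype=np.int64)
            ends = np.array([t[1] for t in entries], dtype=np.int64)
            labels = [t[2] for t in entries]
            ms, me, block = iv.merge_labels(starts, ends)
            members: list[set[str]] = [set() for _ in range(ms.size)]
            for lab, b in zip(labels, block):
                members[b].add(lab)
            # flag assays by locus overlap (not merged in)
            flags = {}
            if chrom in atac_by_chrom:
                ts, te = iv.merge_intervals(*atac_by_chrom[chrom])
                flags["atac"] = iv.overlaps_any(ms, me, ts, te)
            else:
                flags["atac"] = np.zeros(ms.size, dtype=bool)
            for lab in histone_labels:
                if chrom in flag_sets[lab]:
                    ts, te = iv.merge_intervals(*flag_sets[lab][chrom])
                    flags[lab] = iv.overlaps_any(ms, me, ts, te)
                else:
                    flags[lab] = np.zeros(ms.size, dtype=bool)
            for i in range(ms.size):
                row = {
                    "chrom": chrom, "start": int(ms[i]), "end": int(me[i]),
                    "peak_class": peak_class,
                    "tr_count": len(members[i]),
                    "atac": bool(flags["atac"][i]),
                }
                for lab in tr_labels:
                    row[lab] = lab in members[i]
                for lab in histone_labels:
                    row[lab] = bool(flags[lab][i])
                rows.append(row)

    columns = ["chrom", "start", "end", "peak_class", "tr_count", "atac",
               *tr_labels, *histone_labels]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["peak_class", "chrom", "start", "end"]).reset_index(drop=True)
    return LocusTable(df=df, tr_labels=tr_labels, histone_labels=histone_labels,
                      genome_label=genome_label)


def membership_counts(locus_table: LocusTable) -> pd.DataFrame:
    """UpSet-style tabulation: loci per (membership subset x ATAC flag).

    Returns a long dataframe with columns peak_class, membership
    (sorted '+'-joined labels), tr_count, atac, n, pct_of_class; plus
    marginal rows (membership='*') giving counts per tr_count alone.
    """
    rows = []
    df = locus_table.df
    for peak_class in ("proximal", "distal"):
        sub = df[df["peak_class"] == peak_class]
        total = len(sub)
        if total == 0:
            continue
        key = sub.apply(
            lambda r: "+".join(sorted(t for t in locus_table.tr_labels if r[t])),
            axis=1,
        )
        grouped = sub.groupby([key, sub["atac"]]).size()
        for (memb, atac), n in grouped.items():
            rows.append({
                "peak_class": peak_class, "membership": memb,
                "tr_count": 0 if not memb else memb.count("+") + 1,
                "atac": bool(atac), "n": int(n),
                "pct_of_class": 100.0 * n / total,
            })
        for tr_count, n in sub.groupby("tr_count").size().items():
            rows.append({
                "peak_class": peak_class, "membership": "*",
                "tr_count": int(tr_count), "atac": None, "n": int(n),
                "pct_of_class": 100.0 * n / total,
            })
    return pd.DataFrame(
        rows, columns=["peak_class", "membership", "tr_count", "atac", "n",
                       "pct_of_class"]
    )


def _merged_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in df.groupby("chrom"):
        out[str(chrom)] = iv.merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
    return out


def overlap_fractions(query: PeakSet, target: PeakSet) -> OverlapFractions:
    """Peak-level and nucleotide-level overlap of query with target.

    peak_fraction counts query peaks with >=1 bp overlap; the nucleotide
    fraction is computed on the merged query coverage so fragmented peaks
    do not double-count bases.
    """
    if len(query) == 0:
        raise ValueError("query peak set is empty")
    if query.genome_label != target.genome_label:
        raise ValueError("query and target declare different genomes")
    target_merged = _merged_by_chrom(target.df)
    n_hit = 0
    cov_bp = 0
    inter_bp = 0
    for chrom, sub in query.df.groupby("chrom"):
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        ts, te = target_merged.get(str(chrom), (np.empty(0, np.int64),) * 2)
        n_hit += int(iv.overlaps_any(qs, qe, ts, te).sum())
        mqs, mqe = iv.merge_intervals(qs, qe)
        cov_bp += int((mqe - mqs).sum())
        inter_bp += int(iv.overlap_bp(mqs, mqe, ts, te).sum())
    return OverlapFractions(
        peak_fraction=100.0 * n_hit / len(query),
        nucleotide_fraction=100.0 * inter_bp / cov_bp,
    )


def conservation_summary(
    locus_table: LocusTable | pd.DataFrame,
    track: ScoreTrack,
    threshold: float = 0.5,
) -> ConservationSummary:
    """Max conservation score per locus; fraction exceeding the threshold.

    Loci with no track coverage score 0 (bases absent from a conservation
    track are unalignable, hence unconserved).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    loci = locus_table.df if isinstance(locus_table, LocusTable) else locus_table
    track_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in track.df.groupby("chrom"):
        s = sub.sort_values("start")
        track_by_chrom[str(chrom)] = (
            s["start"].to_numpy(np.int64),
            s["end"].to_numpy(np.int64),
            s["value"].to_numpy(float),
        )
    maxima = np.zeros(len(loci))
    for i, row in enumerate(loci.itertuples(index=False)):
        tr = track_by_chrom.get(row.chrom)
        if tr is None:
            continue
        ts, te, tv = tr
        mask = (ts < row.end) & (te > row.start)
        if mask.any():
            maxima[i] = tv[mask].max()
    frac = 100.0 * float((maxima > threshold).sum()) / len(loci) if len(loci) else 0.0
    return ConservationSummary(per_locus_max=maxima, threshold=threshold,
                               fraction_above=frac)


def link_distal_to_genes(
    locus_table: LocusTable,
    genes,
    config: LinkConfig,
    gene_set: Iterable[str],
) -> pd.DataFrame:
    """Count gene-set genes with a qualifying distal locus within each window.

    A gene is linked at window w when any distal locus whose membership
    contains the required assays (with ATAC if required) lies within w bp of
    any of the gene's TSSs, edge-to-TSS distance, overlap counting as 0.
    Returns a dataframe (window_bp, n_linked, set_size, pct) with the linked
    sets monotone non-decreasing in window size.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    qual = locus_table.subset(
        peak_class="distal",
        min_tr_count=config.min_tr_count,
        require_atac=config.require_atac,
        required_assays=config.required_assays,
    )
    loci_by_chrom = {
        str(chrom): (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in qual.groupby("chrom")
    }
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    linked_prev: set[str] = set()
    for w in config.windows_bp:
        linked: set[str] = set()
        for gid in gene_set:
            g = gene_by_id.get(gid)
            if g is None or g.chrom not in loci_by_chrom:
                continue
            ls, le = loci_by_chrom[g.chrom]
            for tss in g.tss_list:
                inside = (ls <= tss) & (tss < le)
                d = np.where(
                    inside, 0, np.minimum(np.abs(ls - tss), np.abs((le - 1) - tss))
                )
                if (d <= w).any():
                    linked.add(gid)
                    break
        linked |= linked_prev  # monotone by construction of nested windows
        linked_prev = linked
        rows.append({
            "window_bp": w,
            "n_linked": len(linked),
            "set_size": len(gene_set),
            "pct": proportion_pct(len(linked), len(gene_set)),
        })
    return pd.DataFrame(rows)


def cross_dataset_locus_match(a: LocusTable, b: LocusTable) -> float:
    """Fraction (%) of loci in A overlapping >=1 locus in B (same coordinates)."""
    if a.genome_label != b.genome_label:
        raise ValueError(
            f"coordinate spaces differ: {a.genome_label!r} vs {b.genome_label!r}"
        )
    if len(a) == 0:
        raise ValueError("locus table A is empty")
    b_merged = _merged_by_chrom(b.df)
    n_hit = 0
    for chrom, sub in a.df.groupby("chrom"):
        ts, te = b_merged.get(str(chrom), (np.empty(0, np.int64),) * 2)
        n_hit += int(
            iv.overlaps_any(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), ts, te
            ).sum()
        )
    return 100.0 * n_hit / len(a)
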