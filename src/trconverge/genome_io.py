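"""Core genomic types and plain-text format I/O.

Everything is 0-based half-open internally (BED convention). Chromosome
names are compared by exact string match — no "chr" aliasing — so mixing
namespaces surfaces as an error rather than silently empty overlaps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeDef",
    "ScoreTrack",
    "GeneModel",
    "read_narrowpeak",
    "read_bed",
    "write_bed",
    "write_narrowpeak",
    "read_gene_table",
    "read_score_track",
    "write_score_track",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span [start, end), the atom of all overlap computation.

    ``score_neglog10p`` carries the peak caller's -log10 p-value when known;
    the MACS2 sentinel -1 ("unavailable") maps to None, which excludes the
    peak from rank-based operations only.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score_neglog10p: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score_neglog10p is not None and self.score_neglog10p < 0:
            raise ValueError("score_neglog10p must be >= 0 when present")

    @property
    def length(self) -> int:
        return self.end - self.start


_PEAK_COLUMNS = ["chrom", "start", "end", "name", "strand", "score_neglog10p"]


@dataclass
class PeakSet:
    """One assay's peak calls (a TR ChIP-seq, ATAC-seq or histone dataset)."""

    assay_label: str
    df: pd.DataFrame
    genome_label: str = "unspecified"

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "start", "end") if c not in self.df.columns]
        if missing:
            raise ValueError(f"PeakSet dataframe missing columns {missing}")
        df = self.df.copy()
        for col, default in (("name", None), ("strand", "."), ("score_neglog10p", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[_PEAK_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score_neglog10p"] = df["score_neglog10p"].astype(float)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
            raise ValueError(
                f"{self.assay_label}: invalid interval at row {bad}: "
                f"{df.loc[bad, 'chrom']}:[{df.loc[bad, 'start']},{df.loc[bad, 'end']})"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_intervals(
        cls, assay_label: str, intervals: Iterable[GenomicInterval], genome_label: str = "unspecified"
    ) -> "PeakSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, iv.strand,
             np.nan if iv.score_neglog10p is None else iv.score_neglog10p)
            for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
        return cls(assay_label, df, genome_label)

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = []
        for row in self.df.itertuples(index=False):
            score = None if pd.isna(row.score_neglog10p) else float(row.score_neglog10p)
            out.append(
                GenomicInterval(row.chrom, int(row.start), int(row.end),
                                row.strand, row.name, score)
            )
        return out

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            order = np.lexsort((sub["end"].to_numpy(), sub["start"].to_numpy()))
            out[str(chrom)] = (
                sub["start"].to_numpy()[order],
                sub["end"].to_numpy()[order],
            )
        return out


@dataclass
class GenomeDef:
    """Chromosome sizes; required by the length-preserving shuffle null."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    def check_fits(self, peaks: PeakSet) -> None:
        for chrom, sub in peaks.df.groupby("chrom"):
            if chrom not in self.chrom_sizes:
                raise ValueError(f"chromosome {chrom} absent from genome definition")
            if int(sub["end"].max()) > self.chrom_sizes[chrom]:
                raise ValueError(
                    f"{peaks.assay_label}: interval exceeds length of {chrom}"
                )


@dataclass
class ScoreTrack:
    """Per-interval conservation-style scores in [0, 1] (bedGraph-like).

    Intervals within one chromosome must be non-overlapping; bases with no
    interval implicitly score 0 (unalignable bases are unconserved).
    """

    df: pd.DataFrame  # columns chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.df[["chrom", "start", "end", "value"]].copy().reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
            raise ValueError("score track contains invalid intervals")
        if ((df["value"] < 0) | (df["value"] > 1)).any():
            raise ValueError("score track values must lie in [0, 1]")
        for chrom, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"score track intervals overlap on {chrom}")
        self.df = df


@dataclass
class GeneModel:
    """A gene with one or more transcript start sites.

    ``tss_list`` holds 0-based positions of the first transcribed base;
    ``cdna_length`` is the covariate used by length-matched permutation tests.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int]
    cdna_length: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: tss_list is empty")
        if self.cdna_length <= 0:
            raise ValueError(f"gene {self.gene_id}: cdna_length must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_narrowpeak(path: str | Path, assay_label: str | None = None,
                    genome_label: str = "unspecified") -> PeakSet:
    """Read an ENCODE narrowPeak (10 columns) or BED6+ file.

    Column 8 (-log10 p) becomes ``score_neglog10p``; the MACS2 sentinel -1
    becomes missing. Malformed lines raise with the offending line number.
    """
    label = assay_label if assay_label is not None else Path(path).stem
    rows = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            chrom = fields[0]
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not chrom or not (0 <= start < end):
            raise ValueError(
                f"{path}:{lineno}: invalid interval {chrom}:[{start},{end})"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else "."
        score = np.nan
        if len(fields) >= 8:
            try:
                raw = float(fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad -log10 p value") from exc
            if raw < 0 and raw != -1:
                raise ValueError(f"{path}:{lineno}: negative -log10 p value")
            score = np.nan if raw == -1 else raw
        rows.append((chrom, start, end, name, strand, score))
    df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    return PeakSet(label, df, genome_label)


read_bed = read_narrowpeak  # BED3/BED6 are a column-subset of the same grammar


def write_bed(peaks: PeakSet | Sequence[GenomicInterval] | pd.DataFrame,
              path: str | Path) -> None:
    """Write BED (3 or 6 columns); round-trips coordinates exactly."""
    df = _as_frame(peaks)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if row.name is None and row.strand == ".":
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                name = row.name if row.name is not None else "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write 10-column narrowPeak; missing -log10 p becomes the -1 sentinel."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.df.itertuples(index=False)):
            name = row.name if row.name is not None else f"peak_{i}"
            p = -1 if pd.isna(row.score_neglog10p) else row.score_neglog10p
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}"
                f"\t0\t{p:g}\t-1\t-1\n"
            )


def _as_frame(peaks) -> pd.DataFrame:
    if isinstance(peaks, PeakSet):
        return peaks.df
    if isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
        if "name" not in df:
            df["name"] = None
        if "strand" not in df:
            df["strand"] = "."
        return df
    return PeakSet.from_intervals("tmp", peaks).df


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a flattened transcript TSV into per-gene models.

    Required header columns: gene_id, transcript_id, chrom, strand, tss,
    cdna_length, biotype. One GeneModel per gene, aggregating transcript TSSs.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"gene_id", "transcript_id", "chrom", "strand", "tss",
                "cdna_length", "biotype"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if table.empty:
        return []
    dup = table["transcript_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate transcript_id {table.loc[dup, 'transcript_id'].iloc[0]!r}"
        )
    bad = ~table["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"{path}: transcript {table.loc[bad, 'transcript_id'].iloc[0]!r} "
            f"has invalid strand {table.loc[bad, 'strand'].iloc[0]!r}"
        )
    genes = []
    for gene_id, sub in table.groupby("gene_id", sort=True):
        if sub["chrom"].nunique() > 1 or sub["strand"].nunique() > 1:
            raise ValueError(f"{path}: gene {gene_id} spans chromosomes or strands")
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=str(sub["chrom"].iloc[0]),
                strand=str(sub["strand"].iloc[0]),
                tss_list=sorted(int(t) for t in sub["tss"]),
                cdna_length=int(sub["cdna_length"].max()),
                biotype=str(sub["biotype"].iloc[0]),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for i, tss in enumerate(g.tss_list):
            rows.append((g.gene_id, f"{g.gene_id}.t{i + 1}", g.chrom, g.strand,
                         tss, g.cdna_length, g.biotype))
    pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "chrom", "strand", "tss",
                       "cdna_length", "biotype"]
    ).to_csv(path, sep="\t", index=False)


def read_score_track(path: str | Path) -> ScoreTrack:
    """Read a bedGraph-like (chrom, start, end, value) file, no header."""
    rows = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return ScoreTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")
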