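"""Shared fixtures and independent brute-force oracles.

The oracles recompute interval semantics per base (or by exhaustive
pairwise scans), never touching the package's sorted-array kernels, so
they provide a genuinely independent route for equivalence tests on
small random genomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trconverge.genome_io import GeneModel, GenomeDef, PeakSet


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_promoter_bases(gene: GeneModel, window: int, chrom_len: int) -> set[int]:
    """All bases in the gene's merged promoter windows, enumerated one by one."""
    bases: set[int] = set()
    for tss in gene.tss_list:
        if gene.strand == "+":
            lo, hi = tss - window, tss
        else:
            lo, hi = tss + 1, tss + 1 + window
        for b in range(max(lo, 0), min(hi, chrom_len)):
            bases.add(b)
    return bases


def oracle_classify(peak: tuple[str, int, int], genes: list[GeneModel],
                    window: int, chrom_len: int):
    """(class, proximal_genes, distal_gene, distance) by per-base scan."""
    chrom, s, e = peak
    peak_bases = set(range(s, e))
    prox = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        if peak_bases & oracle_promoter_bases(g, window, chrom_len):
            prox.add(g.gene_id)
    if prox:
        return "proximal", prox, None, 0
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        for tss in g.tss_list:
            if s <= tss < e:
                d = 0
            else:
                d = min(abs(tss - s), abs(tss - (e - 1)))
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
    if best is None:
        return "distal", set(), None, -1
    return "distal", set(), best[1], best[0]


def oracle_merge(peaks: list[tuple[int, int, str]]):
    """Connected components of the >=1 bp-overlap graph, exhaustive pairwise.

    peaks: (start, end, label) on one chromosome. Returns a list of
    (start, end, frozenset(labels)) sorted by start.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            si, ei, _ = peaks[i]
            sj, ej, _ = peaks[j]
            if si < ej and sj < ei:  # strict overlap; bookended stay apart
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        s = min(peaks[i][0] for i in members)
        e = max(peaks[i][1] for i in members)
        labs = frozenset(peaks[i][2] for i in members)
        out.append((s, e, labs))
    return sorted(out)


def oracle_max_score(start: int, end: int, track_rows) -> float:
    """Max per-base score over [start, end); rows are (s, e, value)."""
    best = 0.0
    for b in range(start, end):
        for s, e, v in track_rows:
            if s <= b < e:
                best = max(best, v)
    return best


def random_genome_case(rng: np.random.Generator, chrom_len: int = 10_000):
    """A random small single-chromosome test case: genes and TR peaks."""
    n_genes = int(rng.integers(1, 6))
    genes = []
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_tss = int(rng.integers(1, 3))
        tss = sorted(int(t) for t in rng.integers(100, chrom_len - 100, n_tss))
        genes.append(GeneModel(f"g{i:02d}", "chrU", strand, tss,
                               int(rng.integers(200, 5000))))
    labels = ["A", "B", "C"]
    rows_by_label: dict[str, list] = {lab: [] for lab in labels}
    for lab in labels:
        for _ in range(int(rng.integers(0, 11))):
            s = int(rng.integers(0, chrom_len - 10))
            L = int(rng.integers(1, 500))
            rows_by_label[lab].append(
                ("chrU", s, min(s + L, chrom_len), None, ".",
                 float(rng.random() * 10))
            )
    columns = ["chrom", "start", "end", "name", "strand", "score_neglog10p"]
    peaks = {
        lab: PeakSet(lab, pd.DataFrame(rows_by_label[lab], columns=columns))
        for lab in labels
    }
    genome = GenomeDef({"chrU": chrom_len})
    return genes, peaks, genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
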