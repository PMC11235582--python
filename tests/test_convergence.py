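"""Locus merging, membership counts, overlap fractions, conservation, linking."""

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_max_score, oracle_merge, random_genome_case
from trconverge.annotate import build_promoters, classify_peaks
from trconverge.convergence import (
    LinkConfig,
    LocusTable,
    conservation_summary,
    cross_dataset_locus_match,
    link_distal_to_genes,
    membership_counts,
    merge_loci,
    overlap_fractions,
    proportion_pct,
)
from trconverge.genome_io import GeneModel, GenomeDef, PeakSet, ScoreTrack


def _ps(label, rows, genome_label="g"):
    return PeakSet(label, pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                   genome_label)


def _annotate_all(peaks, genes, window=500):
    pm = build_promoters(genes, window)
    return pm, {ps.assay_label: classify_peaks(ps, pm, genes) for ps in peaks}


FAR_GENE = [GeneModel("gZ", "chrU", "+", [9_000], 100)]  # keeps peaks distal


class TestMergeLoci:
    def test_five_coincident_peaks_one_5tra_locus(self):
        trs = [_ps(lab, [("chrU", 100, 200)]) for lab in "ABCDE"]
        atac = _ps("ATAC", [("chrU", 150, 160)])
        _, anns = _annotate_all(trs, FAR_GENE)
        table = merge_loci(trs, atac, anns)
        assert len(table) == 1
        row = table.df.iloc[0]
        assert row.tr_count == 5 and row.atac
        assert (row.start, row.end) == (100, 200)

    def test_chained_overlap_merges_transitively(self):
        trs = [_ps("A", [("chrU", 0, 10)]), _ps("B", [("chrU", 5, 15)]),
               _ps("C", [("chrU", 14, 20)])]
        _, anns = _annotate_all(trs, FAR_GENE)
        table = merge_loci(trs, None, anns)
        assert len(table) == 1
        row = table.df.iloc[0]
        assert (row.start, row.end) == (0, 20)
        assert table.membership(0) == frozenset("ABC")

    def test_bookended_peaks_do_not_merge(self):
        trs = [_ps("A", [("chrU", 0, 10)]), _ps("B", [("chrU", 10, 20)])]
        _, anns = _annotate_all(trs, FAR_GENE)
        table = merge_loci(trs, None, anns)
        assert len(table) == 2
        assert (table.df["tr_count"] == 1).all()

    def test_mixed_genome_labels_error(self):
        trs = [_ps("A", [("chrU", 0, 10)], "hg"), _ps("B", [("chrU", 0, 10)], "mm")]
        _, anns = _annotate_all(trs, FAR_GENE)
        with pytest.raises(ValueError, match="mixed genome"):
            merge_loci(trs, None, anns)

    def test_matches_brute_force_components_on_random_input(self):
        rng = np.random.default_rng(4242)
        for _ in range(25):
            genes, peaks, genome = random_genome_case(rng)
            pm, anns = _annotate_all(list(peaks.values()), genes)
            table = merge_loci(list(peaks.values()), None, anns)
            for peak_class in ("proximal", "distal"):
                tagged = []
                for lab, ps in peaks.items():
                    cls = anns[lab].table["peak_class"].to_numpy()
                    for k, row in enumerate(ps.df.itertuples(index=False)):
                        if cls[k] == peak_class:
                            tagged.append((int(row.start), int(row.end), lab))
                expect = oracle_merge(tagged)
                got = [
                    (int(r.start), int(r.end),
                     frozenset(t for t in table.tr_labels if getattr(r, t)))
                    for r in table.df[table.df["peak_class"] == peak_class]
                    .itertuples(index=False)
                ]
                assert sorted(got) == expect


class TestMembershipCounts:
    def test_partition_sums_to_locus_count(self):
        rng = np.random.default_rng(11)
        genes, peaks, _ = random_genome_case(rng)
        _, anns = _annotate_all(list(peaks.values()), genes)
        table = merge_loci(list(peaks.values()), None, anns)
        counts = membership_counts(table)
        subsets = counts[counts["membership"] != "*"]
        assert subsets["n"].sum() == len(table)
        marginals = counts[counts["membership"] == "*"]
        assert marginals["n"].sum() == len(table)

    def test_printed_ratio_recovery(self):
        # a locus table carrying published-scale counts reproduces the
        # published percentage summaries
        labels = list("ABCDE")
        rows = []
        pos = 0

        def add(n, tr_count, atac):
            nonlocal pos
            for _ in range(n):
                r = {"chrom": "chr1", "start": pos, "end": pos + 10,
                     "peak_class": "proximal", "tr_count": tr_count,
                     "atac": atac}
                for i, lab in enumerate(labels):
                    r[lab] = i < tr_count
                rows.append(r)
                pos += 20

        add(12_224, 5, True)
        add(12_347 - 12_224, 5, False)
        add(882, 1, True)
        add(10_736 - 882, 1, False)
        add(32_962 - 12_347 - 10_736, 3, False)
        table = LocusTable(pd.DataFrame(rows), labels, [])
        counts = membership_counts(table)
        marg = counts[counts["membership"] == "*"].set_index("tr_count")
        assert marg.loc[5, "n"] == 12_347
        assert round(marg.loc[5, "pct_of_class"], 1) == 37.5
        five = counts[(counts["tr_count"] == 5) & (counts["atac"] == True)]
        assert round(100.0 * five["n"].sum() / marg.loc[5, "n"], 1) == 99.0
        one_atac = counts[(counts["tr_count"] == 1) & (counts["atac"] == True)]
        assert round(100.0 * one_atac["n"].sum() / marg.loc[1, "n"], 1) == 8.2

    def test_empty_table(self):
        table = LocusTable(
            pd.DataFrame(columns=["chrom", "start", "end", "peak_class",
                                  "tr_count", "atac", "A"]), ["A"], [])
        assert membership_counts(table).empty


class TestOverlapFractions:
    def test_identity_and_disjoint(self):
        a = _ps("a", [("chrU", 0, 100), ("chrU", 500, 600)])
        res = overlap_fractions(a, a)
        assert (res.peak_fraction, res.nucleotide_fraction) == (100.0, 100.0)
        b = _ps("b", [("chrU", 1000, 1100)])
        res = overlap_fractions(a, b)
        assert (res.peak_fraction, res.nucleotide_fraction) == (0.0, 0.0)

    def test_half_overlap(self):
        a = _ps("a", [("chrU", 0, 100)])
        b = _ps("b", [("chrU", 50, 150)])
        res = overlap_fractions(a, b)
        assert res.peak_fraction == 100.0
        assert res.nucleotide_fraction == 50.0

    def test_invariant_to_target_splitting(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 5_000, 20)
        a = _ps("a", [("chrU", int(s), int(s) + 50) for s in starts])
        b_whole = _ps("b", [("chrU", 1_000, 3_000)])
        b_split = _ps("b", [("chrU", 1_000, 1_700), ("chrU", 1_700, 2_400),
                            ("chrU", 2_400, 3_000)])
        r1 = overlap_fractions(a, b_whole)
        r2 = overlap_fractions(a, b_split)
        assert r1.peak_fraction == r2.peak_fraction
        assert r1.nucleotide_fraction == pytest.approx(r2.nucleotide_fraction)

    def test_empty_query_errors(self):
        a = _ps("a", [])
        b = _ps("b", [("chrU", 0, 10)])
        with pytest.raises(ValueError, match="empty"):
            overlap_fractions(a, b)


def _locus_df(rows):
    labels = ["A", "B", "C"]
    out = []
    for chrom, s, e, cls, memb, atac in rows:
        r = {"chrom": chrom, "start": s, "end": e, "peak_class": cls,
             "tr_count": len(memb), "atac": atac}
        for lab in labels:
            r[lab] = lab in memb
        out.append(r)
    return LocusTable(pd.DataFrame(out), labels, [])


class TestConservation:
    def test_max_and_threshold(self):
        table = _locus_df([("chrU", 0, 100, "proximal", "A", True),
                           ("chrU", 200, 300, "proximal", "A", True)])
        track = ScoreTrack(pd.DataFrame(
            [("chrU", 0, 50, 0.2), ("chrU", 60, 90, 0.9)],
            columns=["chrom", "start", "end", "value"]))
        res = conservation_summary(table, track, 0.5)
        assert res.per_locus_max.tolist() == [0.9, 0.0]  # no coverage -> 0
        assert res.fraction_above == 50.0

    def test_threshold_bounds(self):
        table = _locus_df([("chrU", 0, 10, "proximal", "A", True)])
        track = ScoreTrack(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
        with pytest.raises(ValueError):
            conservation_summary(table, track, 1.5)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            loci = [("chrU", int(s), int(s) + int(rng.integers(5, 80)),
                     "distal", "A", False)
                    for s in rng.integers(0, 900, 8)]
            table = _locus_df(loci)
            pos, rows = 0, []
            while pos < 1_000:
                ln = int(rng.integers(10, 60))
                if rng.random() < 0.7:
                    rows.append(("chrU", pos, pos + ln, float(round(rng.random(), 3))))
                pos += ln + int(rng.integers(0, 30))
            track = ScoreTrack(pd.DataFrame(
                rows, columns=["chrom", "start", "end", "value"]))
            res = conservation_summary(table, track, 0.5)
            for i, (_, s, e, *_rest) in enumerate(loci):
                expect = oracle_max_score(s, e, [(r[1], r[2], r[3]) for r in rows])
                assert res.per_locus_max[i] == pytest.approx(expect)


class TestLinking:
    def _setup(self):
        genes = [GeneModel("g1", "chrU", "+", [100_000], 500),
                 GeneModel("g2", "chrU", "+", [900_000], 500)]
        loci = _locus_df([("chrU", 140_000, 141_000, "distal", "ABC", True)])
        cfg = LinkConfig(windows_bp=(10_000, 50_000, 1_000_000),
                         min_tr_count=3, required_assays=("A", "B", "C"))
        return genes, loci, cfg

    def test_window_linking_and_monotonicity(self):
        genes, loci, cfg = self._setup()
        res = link_distal_to_genes(loci, genes, cfg, {"g1", "g2"})
        assert res["n_linked"].tolist() == [0, 1, 2]  # monotone non-decreasing
        assert res["pct"].tolist() == [0.0, 50.0, 100.0]

    def test_requires_membership_and_atac(self):
        genes, _, cfg = self._setup()
        loci = _locus_df([("chrU", 140_000, 141_000, "distal", "AB", True)])
        res = link_distal_to_genes(loci, genes, cfg, {"g1"})
        assert res["n_linked"].tolist() == [0, 0, 0]

    def test_empty_gene_set_errors(self):
        genes, loci, cfg = self._setup()
        with pytest.raises(ValueError, match="empty"):
            link_distal_to_genes(loci, genes, cfg, set())


class TestCrossMatch:
    def test_identity_disjoint_and_oracle(self):
        a = _locus_df([("chrU", 0, 100, "proximal", "A", True),
                       ("chrU", 500, 600, "proximal", "A", True)])
        assert cross_dataset_locus_match(a, a) == 100.0
        b = _locus_df([("chrU", 5_000, 5_100, "proximal", "A", True)])
        assert cross_dataset_locus_match(a, b) == 0.0

        rng = np.random.default_rng(5)
        rows_a = [("chrU", int(s), int(s) + 30, "distal", "A", False)
                  for s in rng.integers(0, 2_000, 15)]
        rows_b = [("chrU", int(s), int(s) + 30, "distal", "A", False)
                  for s in rng.integers(0, 2_000, 15)]
        ta, tb = _locus_df(rows_a), _locus_df(rows_b)
        expect = 0
        for _, sa, ea, *_r in rows_a:
            if any(sa < eb and sb < ea for _, sb, eb, *_r2 in rows_b):
                expect += 1
        assert cross_dataset_locus_match(ta, tb) == pytest.approx(
            100.0 * expect / len(rows_a))

    def test_mismatched_coordinate_space_errors(self):
        a = _locus_df([("chrU", 0, 10, "distal", "A", False)])
        b = _locus_df([("chrU", 0, 10, "distal", "A", False)])
        b.genome_label = "other"
        with pytest.raises(ValueError, match="coordinate spaces"):
            cross_dataset_locus_match(a, b)


def test_proportion_pct_printed_ratios():
    assert round(proportion_pct(96, 102), 1) == 94.1
    assert round(proportion_pct(77, 102), 1) == 75.5
    with pytest.raises(ValueError):
        proportion_pct(1, 0)
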