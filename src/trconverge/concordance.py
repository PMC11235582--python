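"""Rank-based cross-dataset concordance of peak lists.

Peak lists are sorted by peak-caller p-value (descending -log10 p), ties
broken by genomic location, and truncated to a fixed top N (10,000 proximal
/ 8,000 distal by default) so peak count is not a variable. For a pair of
lists, every peak of A is matched to its best-overlapping peak of B (largest
bp overlap, ties to the better B rank); the matched fraction is the
intersection percentage and Spearman's rho over the matched (rank_A, rank_B)
pairs measures concordance of binding strength.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import PeakSet

__all__ = [
    "RankedPeakList",
    "PairwiseConcordance",
    "PanelComparison",
    "rank_top_n",
    "pairwise_concordance",
    "panel_concordance",
    "compare_panels",
    "TOP_N_PROXIMAL",
    "TOP_N_DISTAL",
]

TOP_N_PROXIMAL = 10_000
TOP_N_DISTAL = 8_000


@dataclass
class RankedPeakList:
    """Top-N peaks of one assay, best (lowest p) first, rank 1-based."""

    assay_label: str
    df: pd.DataFrame  # columns chrom, start, end, score_neglog10p, rank
    n_selected: int

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PairwiseConcordance:
    assay_a: str
    assay_b: str
    n: int
    n_matched: int
    intersect_pct: float
    rho: float | None  # None when < 2 matched pairs


@dataclass
class PanelComparison:
    stats_a: list[float]
    stats_b: list[float]
    wilcoxon_p: float
    exclusions: list[tuple[str, str]]
    method: str  # "exact" or "asymptotic"


def rank_top_n(peakset: PeakSet, n: int) -> RankedPeakList:
    """Deterministic top-N selection by ascending p-value.

    Peaks lacking a -log10 p (the caller's unavailable sentinel) are excluded
    before ranking. Ties in p are broken by (chrom, start, end).
    """
    df = peakset.df.dropna(subset=["score_neglog10p"]).copy()
    if n > len(df):
        raise ValueError(
            f"{peakset.assay_label}: requested top {n} but only {len(df)} "
            "ranked peaks available"
        )
    df = df.sort_values(
        by=["score_neglog10p", "chrom", "start", "end"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).head(n).reset_index(drop=True)
    df["rank"] = np.arange(1, n + 1)
    return RankedPeakList(assay_label=peakset.assay_label,
                          df=df[["chrom", "start", "end", "score_neglog10p", "rank"]],
                          n_selected=n)


def _match(list_a: RankedPeakList, list_b: RankedPeakList) -> np.ndarray:
    """For each A peak, the matched B rank (0 = unmatched).

    Best match = largest bp overlap; ties broken toward the best (smallest)
    B rank. Many-to-one: distinct A peaks may share a B peak.
    """
    out = np.zeros(len(list_a), dtype=np.int64)
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, sub in list_b.df.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        bs = sub["start"].to_numpy(np.int64)[order]
        be = sub["end"].to_numpy(np.int64)[order]
        br = sub["rank"].to_numpy(np.int64)[order]
        maxlen = int((be - bs).max())
        b_by_chrom[str(chrom)] = (bs, be, br, maxlen)
    for i, row in enumerate(list_a.df.itertuples(index=False)):
        entry = b_by_chrom.get(row.chrom)
        if entry is None:
            continue
        bs, be, br, maxlen = entry
        lo = np.searchsorted(bs, row.start - maxlen, side="left")
        hi = np.searchsorted(bs, row.end, side="left")
        if lo == hi:
            continue
        ov = np.minimum(be[lo:hi], row.end) - np.maximum(bs[lo:hi], row.start)
        mask = ov > 0
        if not mask.any():
            continue
        ov = np.where(mask, ov, -1)
        best_ov = ov.max()
        tied = np.flatnonzero(ov == best_ov)
        out[i] = br[lo:hi][tied].min()
    return out


def pairwise_concordance(list_a: RankedPeakList, list_b: RankedPeakList) -> PairwiseConcordance:
    """Intersection % of A's top-N in B's top-N, and Spearman rho of matched ranks."""
    if list_a.n_selected != list_b.n_selected:
        raise ValueError("both lists must be truncated to the same top N")
    matched_b = _match(list_a, list_b)
    hit = matched_b > 0
    n_matched = int(hit.sum())
    rho = None
    if n_matched >= 2:
        ra = list_a.df["rank"].to_numpy()[hit]
        rb = matched_b[hit]
        rho_val = sps.spearmanr(ra, rb).statistic
        rho = None if np.isnan(rho_val) else float(rho_val)
    return PairwiseConcordance(
        assay_a=list_a.assay_label,
        assay_b=list_b.assay_label,
        n=list_a.n_selected,
        n_matched=n_matched,
        intersect_pct=100.0 * n_matched / list_a.n_selected,
        rho=rho,
    )


def panel_concordance(
    peaksets: Sequence[PeakSet], n: int
) -> pd.DataFrame:
    """All-pairs concordance over a panel of peak sets.

    rho is computed once per unordered pair with A = the lexicographically
    lower label (so the matrix is symmetric by construction); the
    intersection percentage is reported in both directions.
    """
    if len(peaksets) < 2:
        raise ValueError("a panel needs >= 2 peak sets")
    ranked = {ps.assay_label: rank_top_n(ps, n) for ps in peaksets}
    labels = sorted(ranked)
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        ab = pairwise_concordance(ranked[la], ranked[lb])
        ba = pairwise_concordance(ranked[lb], ranked[la])
        rows.append({
            "assay_a": la, "assay_b": lb, "n": n,
            "intersect_pct_ab": ab.intersect_pct,
            "intersect_pct_ba": ba.intersect_pct,
            "rho": ab.rho,
        })
    return pd.DataFrame(rows)


def compare_panels(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    statistic: str = "rho",
    exclusions: Iterable[tuple[str, str]] = (),
) -> PanelComparison:
    """Two-sided Wilcoxon rank-sum comparison of pairwise statistics.

    ``panel_a`` / ``panel_b`` are panel_concordance outputs; ``exclusions``
    lists unordered assay pairs to drop (e.g. known cofactor pairs whose
    concordance is trivially high). Exact null when total n <= 25 and no
    ties; normal approximation with tie correction otherwise.
    """
    excl = {frozenset(p) for p in exclusions}

    def values(panel: pd.DataFrame) -> list[float]:
        vals = []
        for row in panel.itertuples(index=False):
            if frozenset((row.assay_a, row.assay_b)) in excl:
                continue
            v = getattr(row, statistic)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                vals.append(float(v))
        return vals

    a, b = values(panel_a), values(panel_b)
    if not a or not b:
        raise ValueError("a panel is empty after exclusions")
    pooled = a + b
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    if len(set(pooled)) == 1:  # fully tied: no evidence of a shift
        p = 1.0
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=False)
        p = float(res.pvalue)
    return PanelComparison(stats_a=a, stats_b=b, wilcoxon_p=p,
                           exclusions=sorted(tuple(sorted(p)) for p in excl),
                           method=method)
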