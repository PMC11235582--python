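"""Statistics for convergence analyses.

Two permutation nulls are central:

* a length-preserving interval shuffle — each query locus is re-placed
  uniformly at random on its own chromosome keeping its length, so overlap
  enrichment is tested while "accounting for size differences";
* a covariate-matched gene-set permutation — null gene sets are drawn
  within covariate (e.g. cDNA length) decile bins, matching the observed
  set's bin profile, which removes confounding of set membership by the
  covariate.

Empirical p-values use the add-one rule p = (1 + #extreme) / (1 + n_perm),
so p is never 0 and is exact under exchangeability. Contingency statistics
follow the conventions used throughout: Pearson chi-squared without
continuity correction, two-sided Fisher by hypergeometric enumeration, and
a flagged Haldane-Anscombe +0.5 adjustment for odds ratios with empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import _intervals as iv
from .genome_io import GenomeDef, PeakSet

__all__ = [
    "PermutationResult",
    "ContingencyResult",
    "DexCriteria",
    "DdctResult",
    "VistaConfig",
    "ROBUST_EXPRESSION_THRESHOLD",
    "shuffle_overlap_test",
    "geneset_permutation_enrich",
    "contingency_test",
    "geneset_fisher_enrich",
    "dex_filter",
    "expression_stratify",
    "vista_tissue_enrichment",
    "ddct",
]

ROBUST_EXPRESSION_THRESHOLD = 1.0  # log2(TPM+1) at or above which a gene is "robust"


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    n_as_extreme: int
    p_empirical: float
    seed: int
    direction: str
    null_mean: float
    null_sd: float
    null_min: float
    null_max: float


@dataclass
class ContingencyResult:
    table: tuple[int, int, int, int]  # a, b, c, d row-major
    chi2: float | None
    p_chi2: float | None
    odds_ratio: float
    or_haldane_adjusted: bool
    p_fisher: float
    N: int


@dataclass
class DexCriteria:
    """Differential-expression thresholds, both inclusive."""

    min_abs_fold_change: float = 2.0
    max_adj_p: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_fold_change <= 1:
            raise ValueError("fold-change threshold must exceed 1")
        if not (0 < self.max_adj_p < 1):
            raise ValueError("adjusted-p threshold must lie in (0, 1)")


@dataclass
class DdctResult:
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    rel_expression: float


@dataclass
class VistaConfig:
    min_positive_per_tissue: int = 50
    correction: str = "fdr_bh"


def _tally(null: np.ndarray, observed: float, direction: str) -> int:
    if direction == "greater":
        return int((null >= observed).sum())
    if direction == "less":
        return int((null <= observed).sum())
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


def _perm_result(observed, null, seed, direction, n_perm) -> PermutationResult:
    k = _tally(null, observed, direction)
    return PermutationResult(
        observed=float(observed),
        n_perm=n_perm,
        n_as_extreme=k,
        p_empirical=(1 + k) / (1 + n_perm),
        seed=seed,
        direction=direction,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        null_min=float(null.min()),
        null_max=float(null.max()),
    )


def shuffle_overlap_test(
    query: PeakSet,
    target: PeakSet,
    genome: GenomeDef,
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "greater",
) -> PermutationResult:
    """Permutation test of query-target locus overlap.

    Statistic: number of query loci with >=1 bp overlap of the (merged)
    target. Null: each query locus is placed uniformly at random on its own
    chromosome with its length preserved; placements are independent and
    shuffled loci may overlap each other.
    """
    genome.check_fits(query)
    genome.check_fits(target)
    target_merged = {
        chrom: iv.merge_intervals(s, e) for chrom, (s, e) in target.by_chrom().items()
    }
    rng = np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_perm, dtype=np.int64)
    for chrom, (qs, qe) in query.by_chrom().items():
        lengths = qe - qs
        size = genome.chrom_sizes[chrom]
        if (lengths > size).any():
            raise ValueError(f"query locus longer than chromosome {chrom}")
        ts, te = target_merged.get(chrom, (np.empty(0, np.int64),) * 2)
        observed += int(iv.overlaps_any(qs, qe, ts, te).sum())
        # vectorized placement: (n_perm, k) uniform starts in [0, size - L]
        span = (size - lengths + 1).astype(np.float64)
        starts = (rng.random((n_perm, lengths.size)) * span).astype(np.int64)
        if ts.size:
            idx = np.searchsorted(te, starts, side="right")
            hit = idx < ts.size
            shuffled_hit = np.zeros(starts.shape, dtype=bool)
            ends = starts + lengths
            shuffled_hit[hit] = ts[idx[hit]] < ends[hit]
            null += shuffled_hit.sum(axis=1)
    return _perm_result(observed, null, seed, direction, n_perm)


def geneset_permutation_enrich(
    universe: Sequence[str],
    gene_set: Iterable[str],
    indicator: Mapping[str, bool] | pd.Series,
    covariate: Mapping[str, float] | pd.Series | None = None,
    n_bins: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "greater",
) -> PermutationResult:
    """Covariate-matched permutation test of gene-set enrichment.

    Statistic: number of gene-set genes whose indicator is true. Null sets
    are drawn by sampling, within each covariate quantile bin, the same
    number of genes as the set contributes to that bin (without
    replacement). ``n_bins=1`` (or ``covariate=None``) gives the unmatched
    test — simple random gene sets of the same size.
    """
    universe = list(universe)
    gene_set = set(gene_set)
    missing = gene_set - set(universe)
    if missing:
        raise ValueError(f"gene_set members absent from universe: {sorted(missing)[:5]}")
    ind = pd.Series(indicator).reindex(universe)
    if ind.isna().any():
        raise ValueError("indicator missing for some universe genes")
    ind_arr = ind.to_numpy(dtype=bool)
    in_set = np.array([g in gene_set for g in universe])
    observed = int(ind_arr[in_set].sum())

    if covariate is None or n_bins <= 1:
        bins = np.zeros(len(universe), dtype=np.int64)
        n_bins = 1
    else:
        cov = pd.Series(covariate).reindex(universe)
        if cov.isna().any():
            raise ValueError("covariate missing for some universe genes")
        bins = pd.qcut(cov.rank(method="first"), q=n_bins, labels=False).to_numpy()

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    for b in range(int(bins.max()) + 1):
        members = np.flatnonzero(bins == b)
        k = int(in_set[members].sum())
        if k == 0:
            continue
        if k > members.size:
            raise ValueError(
                f"covariate bin {b} has {members.size} genes but the set needs "
                f"{k}; use fewer bins"
            )
        bin_ind = ind_arr[members]
        # sample k without replacement, n_perm times, via random-key argpartition
        keys = rng.random((n_perm, members.size))
        chosen = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null += bin_ind[chosen].sum(axis=1)
    return _perm_result(observed, null, seed, direction, n_perm)


def contingency_test(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """2x2 association: Pearson chi-squared (no continuity correction),
    odds ratio ad/bc, and two-sided Fisher exact p."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        chi2 = p_chi2 = None
    else:
        chi2 = N * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        p_chi2 = float(sps.chi2.sf(chi2, df=1))
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    p_fisher = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return ContingencyResult(
        table=(a, b, c, d),
        chi2=None if chi2 is None else float(chi2),
        p_chi2=p_chi2,
        odds_ratio=float(odds),
        or_haldane_adjusted=haldane,
        p_fisher=p_fisher,
        N=N,
    )


def geneset_fisher_enrich(
    target_set: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Fisher enrichment of a target gene list in each of several gene sets.

    One 2x2 per set (in/out of target x in/out of set) over the universe;
    corrected p by Bonferroni (default) or Benjamini-Hochberg FDR.
    Returns a dataframe: set, a, b, c, d, odds_ratio, p, p_adj, method.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target = set(target_set) & universe
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & universe
        a = len(target & gs)
        b = len(target - gs)
        c = len(gs - target)
        d = len(universe) - a - b - c
        res = contingency_test(a, b, c, d)
        rows.append({"set": name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": res.odds_ratio, "p": res.p_fisher})
    df = pd.DataFrame(rows)
    if correction not in ("bonferroni", "fdr_bh"):
        raise ValueError("correction must be 'bonferroni' or 'fdr_bh'")
    if len(df):
        df["p_adj"] = multipletests(df["p"], method=correction)[1]
    else:
        df["p_adj"] = []
    df["method"] = correction
    return df


def dex_filter(
    dge_table: pd.DataFrame, criteria: DexCriteria = DexCriteria()
) -> tuple[set[str], set[str]]:
    """Split a DGE table into up/down-regulated gene sets.

    Requires columns gene, log2fc, padj. Thresholds are inclusive:
    |fold change| >= min_abs_fold_change and adjusted p <= max_adj_p.
    """
    missing = {"gene", "log2fc", "padj"} - set(dge_table.columns)
    if missing:
        raise ValueError(f"DGE table missing columns {sorted(missing)}")
    lfc_cut = np.log2(criteria.min_abs_fold_change)
    sig = dge_table["padj"] <= criteria.max_adj_p
    up = set(dge_table.loc[sig & (dge_table["log2fc"] >= lfc_cut), "gene"])
    down = set(dge_table.loc[sig & (dge_table["log2fc"] <= -lfc_cut), "gene"])
    return up, down


def expression_stratify(
    genes,
    expression: Mapping[str, float] | pd.Series,
    locus_table,
    promoters,
    distal_linked: Iterable[str] = (),
    fit_model: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Summarise expression by proximal TR count, ATAC, and distal linkage.

    Per gene the proximal TR count is the size of the union of TR
    memberships over proximal loci overlapping its promoter windows, and
    the ATAC flag is true when any such locus carries one. Strata report n,
    median and quartiles of log2(TPM+1), and the fraction robustly expressed
    (>= 1). When ``fit_model``, a maximum-likelihood logistic regression of
    (robust) on stratum indicators is fitted and returned as a coefficient
    table (term, coef, se, wald_p); None when the fit is degenerate.
    """
    import statsmodels.api as sm

    expr = pd.Series(expression)
    loci = locus_table.df
    prox = loci[loci["peak_class"] == "proximal"]
    by_chrom = {}
    for chrom, sub in prox.groupby("chrom"):
        by_chrom[str(chrom)] = sub
    distal_linked = set(distal_linked)

    rows = []
    for g in genes:
        if g.gene_id not in expr.index:
            continue
        w = promoters.windows[g.gene_id]
        tr_union: set[str] = set()
        atac = False
        sub = by_chrom.get(g.chrom)
        if sub is not None and not w.empty:
            ls = sub["start"].to_numpy(np.int64)
            le = sub["end"].to_numpy(np.int64)
            for s, e in zip(w["start"].to_numpy(), w["end"].to_numpy()):
                hits = np.flatnonzero((ls < e) & (le > s))
                for h in hits:
                    row = sub.iloc[h]
                    tr_union.update(t for t in locus_table.tr_labels if row[t])
                    atac = atac or bool(row["atac"])
        rows.append({
            "gene_id": g.gene_id,
            "tr_count": len(tr_union),
            "atac": atac,
            "distal": g.gene_id in distal_linked,
            "log2_tpm1": float(expr[g.gene_id]),
        })
    per_gene = pd.DataFrame(rows)
    per_gene["robust"] = per_gene["log2_tpm1"] >= ROBUST_EXPRESSION_THRESHOLD

    summaries = (
        per_gene.groupby(["tr_count", "atac", "distal"])
        .agg(
            n=("log2_tpm1", "size"),
            median=("log2_tpm1", "median"),
            q1=("log2_tpm1", lambda x: float(np.quantile(x, 0.25))),
            q3=("log2_tpm1", lambda x: float(np.quantile(x, 0.75))),
            frac_robust=("robust", "mean"),
        )
        .reset_index()
    )

    coef_table = None
    if fit_model and per_gene["robust"].nunique() == 2:
        X = pd.get_dummies(
            per_gene["tr_count"].astype("category"), prefix="tr", drop_first=True
        ).astype(float)
        X["atac"] = per_gene["atac"].astype(float)
        X["distal"] = per_gene["distal"].astype(float)
        X = sm.add_constant(X, has_constant="add")
        try:
            import warnings

            with warnings.catch_warnings():
                # near-separation is expected when low-TR strata are uniformly
                # weakly expressed; the MLE still converges or raises
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = sm.Logit(per_gene["robust"].astype(float), X).fit(disp=0, maxiter=200)
            coef_table = pd.DataFrame({
                "term": X.columns,
                "coef": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(),
                "wald_p": fit.pvalues.to_numpy(),
            })
        except Exception:
            coef_table = None
    return summaries, coef_table


def vista_tissue_enrichment(
    vista_table: pd.DataFrame,
    qualifying_loci: pd.DataFrame,
    tissue_columns: Sequence[str],
    config: VistaConfig = VistaConfig(),
) -> pd.DataFrame:
    """Per-tissue Fisher test of enhancer activity vs locus overlap.

    ``vista_table`` needs element coordinates (chrom, start, end) plus one
    boolean column per tissue; tissues with fewer than
    ``min_positive_per_tissue`` positives are excluded. For each retained
    tissue a 2x2 of (element overlaps a qualifying locus) x (positive in
    tissue) yields a two-sided Fisher p and odds ratio, BH-FDR corrected
    across tissues.
    """
    loci_by_chrom = {
        str(chrom): iv.merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        for chrom, sub in qualifying_loci.groupby("chrom")
    }
    hit = np.zeros(len(vista_table), dtype=bool)
    for i, row in enumerate(vista_table.itertuples(index=False)):
        ts, te = loci_by_chrom.get(row.chrom, (np.empty(0, np.int64),) * 2)
        hit[i] = bool(
            iv.overlaps_any(np.array([row.start]), np.array([row.end]), ts, te)[0]
        )
    rows = []
    for tissue in tissue_columns:
        pos = vista_table[tissue].to_numpy(dtype=bool)
        if int(pos.sum()) < config.min_positive_per_tissue:
            continue
        a = int((hit & pos).sum())
        b = int((hit & ~pos).sum())
        c = int((~hit & pos).sum())
        d = int((~hit & ~pos).sum())
        res = contingency_test(a, b, c, d)
        rows.append({
            "tissue": tissue, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": res.odds_ratio,
            "or_haldane_adjusted": res.or_haldane_adjusted,
            "p": res.p_fisher,
        })
    if not rows:
        raise ValueError(
            f"no tissue has >= {config.min_positive_per_tissue} positive elements"
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method=config.correction)[1]
    return df


def _mean_ct(ct) -> float:
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    if not np.isfinite(arr).all():
        raise ValueError("Ct values must be finite")
    return float(arr.mean())


def ddct(
    ct_target_treated,
    ct_housekeeping_treated,
    ct_target_control,
    ct_housekeeping_control,
) -> DdctResult:
    """Relative qPCR quantification by the delta-delta-Ct method.

    Multiple housekeeping genes are combined by the arithmetic mean of
    their Ct. rel_expression = 2 ** (-ddCt); ddCt = 0 gives fold 1.
    """
    d_treated = _mean_ct(ct_target_treated) - _mean_ct(ct_housekeeping_treated)
    d_control = _mean_ct(ct_target_control) - _mean_ct(ct_housekeeping_control)
    dd = d_treated - d_control
    return DdctResult(
        delta_ct_treated=d_treated,
        delta_ct_control=d_control,
        delta_delta_ct=dd,
        rel_expression=float(2.0 ** (-dd)),
    )
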