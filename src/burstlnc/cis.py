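"""Discovery of candidate cis-functioning lncRNAs.

Two complementary routes, both against permutation backgrounds built by
relocating each lncRNA to random gene positions:

1. *population route*: the allelic score
   ``AI_lnc + AI_mRNA - |AI_lnc - AI_mRNA|`` rewards pairs skewed toward the
   same parental allele; its null distribution comes from re-pairing the
   lncRNA's allelic imbalance with mRNAs around random genomic locations.
2. *single-cell route*: per-allele detection co-occurrence across cells,
   tested per pair with Fisher's exact test (BH-adjusted), with the same
   random relocations providing the background p distribution.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .containers import AllelicCountSet, GeneTable
from .qc import allelic_imbalance

__all__ = [
    "cis_eligible_genes",
    "enumerate_pairs",
    "allelic_score",
    "aggregate_allelic_imbalance",
    "score_permutation",
    "fisher_coordination",
    "coordination_background",
    "coordination_significance",
    "rank_interactions",
]

ALLOWED_BIOTYPES = {
    "protein_coding", "lncRNA", "pseudogene",
    "transcribed_processed_pseudogene", "transcribed_unitary_pseudogene",
    "unitary_pseudogene", "unprocessed_pseudogene",
    "transcribed_unprocessed_pseudogene",
}


def cis_eligible_genes(cs: AllelicCountSet, genes: GeneTable, *,
                       min_allelic_reads: int = 3, min_cells: int = 20) -> pd.Index:
    """Genes eligible for cis analysis.

    Requires >= ``min_allelic_reads`` allelic reads in >= ``min_cells``
    cells, non-imprinted, autosomal, and an allowed biotype.
    """
    allelic = cs.cast_reads + cs.c57_reads
    enough = (allelic >= min_allelic_reads).sum(axis=1) >= min_cells
    t = genes.table
    ok = (
        ~t["imprinted"] & ~t["x_linked"] & t["biotype"].isin(ALLOWED_BIOTYPES)
    )
    return cs.genes[enough].intersection(t.index[ok])


def enumerate_pairs(lnc_ids, genes: GeneTable, eligible: pd.Index, *,
                    window: int = 500_000) -> pd.DataFrame:
    """All (lncRNA, mRNA) pairs with TSSs within ``window`` bp on one chromosome."""
    t = genes.table
    rows = []
    mrna = [g for g in eligible if t.at[g, "biotype"] == "protein_coding"]
    for lnc in lnc_ids:
        lt, lc = t.at[lnc, "tss"], t.at[lnc, "chrom"]
        for m in mrna:
            if t.at[m, "chrom"] != lc:
                continue
            d = abs(int(t.at[m, "tss"]) - int(lt))
            if d <= window and m != lnc:
                rows.append((lnc, m, d))
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "tss_distance"])


def allelic_score(ai_lnc: float, ai_mrna: float) -> float:
    """Coordination score: AI_lnc + AI_mRNA - |AI_lnc - AI_mRNA|.

    Maximal when both genes are skewed toward CAST by the same amount;
    negative when both skew C57 or when the skews disagree.
    """
    return ai_lnc + ai_mrna - abs(ai_lnc - ai_mrna)


def aggregate_allelic_imbalance(cs: AllelicCountSet) -> pd.Series:
    """Per-gene allelic imbalance from read counts aggregated over cells."""
    cast = cs.cast_reads.sum(axis=1).to_numpy(dtype=float)
    c57 = cs.c57_reads.sum(axis=1).to_numpy(dtype=float)
    return pd.Series(allelic_imbalance(cast, c57), index=cs.genes)


def _random_locations(genes: GeneTable, eligible: pd.Index, n_locations: int,
                      window: int, min_neighbours: int, rng) -> list:
    """Random gene positions with at least ``min_neighbours`` eligible genes
    within the window; drawn once and shared by all lncRNAs."""
    t = genes.table
    candidates = []
    for g in eligible:
        chrom, tss = t.at[g, "chrom"], int(t.at[g, "tss"])
        near = t.loc[list(eligible)]
        n_near = (
            (near["chrom"] == chrom)
            & ((near["tss"] - tss).abs() <= window)
            & (near.index != g)
        ).sum()
        if n_near >= min_neighbours:
            candidates.append(g)
    if not candidates:
        raise ValueError("no eligible random locations with enough neighbours")
    picks = rng.choice(len(candidates), size=n_locations, replace=True)
    return [candidates[i] for i in picks]


def score_permutation(cs: AllelicCountSet, genes: GeneTable, lnc_ids, *,
                      window: int = 500_000, n_locations: int = 1_000,
                      min_neighbours: int = 2, seed: int = 0,
                      min_allelic_reads: int = 3, min_cells: int = 20,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Population-route test: allelic score against relocated-gene nulls.

    For each real pair, p is the fraction of random pairs (the lncRNA's AI
    re-paired with every eligible mRNA around each of the shared random
    locations) whose score is >= the real score. Ties count against the real
    pair. The minimum attainable p (one over the number of random pairs) is
    reported alongside; no pseudocount is added.
    """
    rng = np.random.default_rng(seed)
    eligible = cis_eligible_genes(cs, genes, min_allelic_reads=min_allelic_reads,
                                  min_cells=min_cells)
    ai = aggregate_allelic_imbalance(cs)
    t = genes.table
    lnc_ids = [g for g in lnc_ids if g in eligible]
    pairs = enumerate_pairs(lnc_ids, genes, eligible, window=window)
    locations = _random_locations(genes, eligible, n_locations, window,
                                  min_neighbours, rng)
    # mRNAs near each random location, shared across lncRNAs
    mrna_eligible = pd.Index([g for g in eligible if t.at[g, "biotype"] == "protein_coding"])
    near_mrnas = {}
    for loc in set(locations):
        chrom, tss = t.at[loc, "chrom"], int(t.at[loc, "tss"])
        sub = t.loc[mrna_eligible]
        sel = sub.index[(sub["chrom"] == chrom)
                        & ((sub["tss"] - tss).abs() <= window)
                        & (sub.index != loc)]
        near_mrnas[loc] = sel

    rows = []
    for lnc in lnc_ids:
        random_ai = np.concatenate([
            ai[near_mrnas[loc]].to_numpy(dtype=float) for loc in locations
        ]) if locations else np.array([])
        random_ai = random_ai[~np.isnan(random_ai)]
        if len(random_ai) == 0:
            warnings.warn(f"lncRNA {lnc}: no random pairs; skipped", stacklevel=2)
            continue
        ai_l = ai[lnc]
        random_scores = ai_l + random_ai - np.abs(ai_l - random_ai)
        sub = pairs[pairs["lnc_id"] == lnc]
        for _, row in sub.iterrows():
            s = allelic_score(ai_l, ai[row["mrna_id"]])
            p = float(np.mean(random_scores >= s))
            rows.append((lnc, row["mrna_id"], row["tss_distance"], s, p,
                         1.0 / len(random_scores), p < alpha))
    return pd.DataFrame(rows, columns=[
        "lnc_id", "mrna_id", "tss_distance", "allelic_score", "p_perm",
        "min_attainable_p", "significant",
    ])


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _detection(cs: AllelicCountSet, allele: str, min_reads: int) -> pd.DataFrame:
    layer = cs.cast_reads if allele == "CAST" else cs.c57_reads
    return layer >= min_reads


def _pair_tables(det: pd.DataFrame, lnc_id: str, mrna_ids) -> np.ndarray:
    """2x2 co-detection tables for one lncRNA against many mRNAs, via matmul."""
    dl = det.loc[lnc_id].to_numpy()
    dm = det.loc[list(mrna_ids)].to_numpy()
    n = dl.size
    a = dm.astype(np.int64) @ dl.astype(np.int64)
    row_m = dm.sum(axis=1)
    b = int(dl.sum()) - a
    c = row_m - a
    d = n - a - b - c
    return np.column_stack([a, b, c, d])


def _fisher_p_tables(tables: np.ndarray) -> np.ndarray:
    """Fisher two-sided p for a stack of tables; duplicates computed once."""
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    ps = np.empty(len(uniq))
    for i, (a, b, c, d) in enumerate(uniq):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            ps[i] = 1.0
        else:
            ps[i] = _fisher_p(int(a), int(b), int(c), int(d))
    return ps[inverse]


def fisher_coordination(cs: AllelicCountSet, pairs: pd.DataFrame, allele: str, *,
                        min_reads: int = 3) -> pd.DataFrame:
    """Per-allele detection co-occurrence, Fisher's exact test per pair.

    Detection is >= ``min_reads`` allelic reads on the given allele per cell.
    The two-sided p on the 2x2 cell-count table {lnc on/off} x {mRNA on/off}
    is BH-adjusted across all pairs. Degenerate margins (a gene never or
    always detected) give p = 1 with a flag.
    """
    det = _detection(cs, allele, min_reads)
    ps, degen, odds = [], [], []
    for lnc, sub in pairs.groupby("lnc_id", sort=False):
        tables = _pair_tables(det, lnc, sub["mrna_id"])
        pvals = _fisher_p_tables(tables)
        for (a, b, c, d), p in zip(tables, pvals):
            bad = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
            degen.append(bool(bad))
            ps.append(float(p))
            with np.errstate(divide="ignore"):
                odds.append(np.nan if bad else
                            ((a * d) / (b * c) if b * c > 0 else np.inf))
    pairs = pd.concat([sub for _, sub in pairs.groupby("lnc_id", sort=False)])
    out = pairs.copy()
    out["allele"] = allele
    out["p_real"] = ps
    out["odds_ratio"] = odds
    out["degenerate"] = degen
    out["p_real_adj"] = multipletests(ps, method="fdr_bh")[1] if len(ps) else []
    return out


def coordination_background(cs: AllelicCountSet, genes: GeneTable, lnc_ids, allele: str, *,
                            window: int = 500_000, n_locations: int = 1_000,
                            min_neighbours: int = 2, seed: int = 0,
                            min_allelic_reads: int = 3, min_cells: int = 20) -> dict:
    """Random-relocation background p distribution per lncRNA (one allele).

    Each lncRNA's detection vector is paired with the eligible mRNAs around
    the shared random locations; the Fisher p-values of those random pairs
    are BH-adjusted per lncRNA and returned as the background set.
    """
    rng = np.random.default_rng(seed)
    eligible = cis_eligible_genes(cs, genes, min_allelic_reads=min_allelic_reads,
                                  min_cells=min_cells)
    t = genes.table
    locations = _random_locations(genes, eligible, n_locations, window,
                                  min_neighbours, rng)
    mrna_eligible = pd.Index([g for g in eligible if t.at[g, "biotype"] == "protein_coding"])
    near = {}
    for loc in set(locations):
        chrom, tss = t.at[loc, "chrom"], int(t.at[loc, "tss"])
        sub = t.loc[mrna_eligible]
        near[loc] = sub.index[(sub["chrom"] == chrom)
                              & ((sub["tss"] - tss).abs() <= window)
                              & (sub.index != loc)]
    det = _detection(cs, allele, min_allelic_reads)
    background_mrnas: list = []
    for loc in locations:
        background_mrnas.extend(near[loc])
    out = {}
    for lnc in lnc_ids:
        if lnc not in det.index:
            continue
        if background_mrnas:
            tables = _pair_tables(det, lnc, background_mrnas)
            out[lnc] = multipletests(_fisher_p_tables(tables), method="fdr_bh")[1]
        else:
            out[lnc] = np.array([])
    return out


def coordination_significance(real: pd.DataFrame, background: dict, *,
                              alpha: float = 0.01,
                              background_fraction: float = 0.01) -> pd.DataFrame:
    """Call significance: adjusted p_real < 0.01 with < 1% of the lncRNA's
    random-pair adjusted p-values below it."""
    out = real.copy()
    fracs, sig = [], []
    for _, row in out.iterrows():
        bg = background.get(row["lnc_id"], np.array([]))
        frac = float(np.mean(bg < row["p_real_adj"])) if len(bg) else np.nan
        fracs.append(frac)
        sig.append(bool(row["p_real_adj"] < alpha
                        and len(bg) > 0 and frac < background_fraction))
    out["background_fraction_below"] = fracs
    out["significant"] = sig
    return out


def rank_interactions(pairs: pd.DataFrame, ai: pd.Series) -> pd.DataFrame:
    """Order significant pairs by coordination value.

    Alleles are first aligned to the lncRNA's dominant allele (the lncRNA AI
    made positive, the mRNA AI flipped with it), then the allelic score of
    the aligned pair is the ranking value: positive when both genes skew the
    same allele — including joint C57 skew — and negative when they disagree.
    """
    rows = []
    for _, row in pairs.iterrows():
        ai_l = float(ai[row["lnc_id"]])
        ai_m = float(ai[row["mrna_id"]])
        sign = -1.0 if ai_l < 0 else 1.0
        val = allelic_score(sign * ai_l, sign * ai_m)
        rows.append(val)
    out = pairs.copy()
    out["ranking_value"] = rows
    return out.sort_values("ranking_value", ascending=False, kind="mergesort")
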