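"""Locus classification by promoter architecture and TSS-distance structure.

Gene pairs transcribed divergently from closely spaced promoters behave
differently from isolated loci, so the pipeline classifies every expressed
gene by its promoter neighbourhood before the variability and kinetics
analyses (which use only well-separated transcriptional units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneTable, ValidationError

__all__ = ["classify_loci", "promoter_pair_classes", "expression_vs_tss_distance"]


def _tss_frame(genes: GeneTable, expressed) -> pd.DataFrame:
    t = genes.table
    expressed = pd.Index(expressed)
    unknown = expressed.difference(t.index)
    if len(unknown):
        raise ValidationError(f"expressed genes not in annotation: {list(unknown[:5])}")
    return t.loc[expressed]


def _nearest_expressed_tss(genes: GeneTable, expressed) -> pd.Series:
    """Distance from each expressed gene's TSS to the nearest other expressed TSS."""
    t = _tss_frame(genes, expressed)
    out = pd.Series(np.inf, index=t.index)
    partner = pd.Series("", index=t.index, dtype=object)
    for _, sub in t.groupby("chrom", sort=False):
        if len(sub) < 2:
            continue
        order = sub.sort_values("tss")
        tss = order["tss"].to_numpy(dtype=float)
        ids = order.index.to_numpy()
        left = np.full(len(tss), np.inf)
        right = np.full(len(tss), np.inf)
        left[1:] = tss[1:] - tss[:-1]
        right[:-1] = tss[1:] - tss[:-1]
        nearest = np.minimum(left, right)
        pick_left = left <= right
        pidx = np.where(pick_left, np.arange(len(tss)) - 1, np.arange(len(tss)) + 1)
        out[ids] = nearest
        partner[ids] = ids[np.clip(pidx, 0, len(tss) - 1)]
    return out, partner


def _overlaps(row_a, row_b) -> bool:
    return row_a["chrom"] == row_b["chrom"] and (
        row_a["start"] < row_b["end"] and row_b["start"] < row_a["end"]
    )


def classify_loci(genes: GeneTable, expressed, *, divergent_max: int = 500,
                  convergent_max: int = 2_000, separated_min: int = 4_000) -> pd.DataFrame:
    """Classify expressed loci by promoter architecture.

    Categories, evaluated in order per gene (a gene can be both intergenic
    and a separated unit):

    - ``divergent``: an opposite-strand expressed partner with no gene-body
      overlap and TSS distance <= 500 bp;
    - ``convergent``: an overlapping expressed partner with TSS distance
      <= 2 kb;
    - ``intergenic``: no gene-body overlap with any expressed gene and >= 4 kb
      from any expressed gene;
    - ``separated_unit``: nearest expressed TSS >= 4 kb away.

    Returns a table with columns class, partner, nearest_tss_distance and the
    separated_unit flag.
    """
    t = _tss_frame(genes, expressed)
    nearest, partner = _nearest_expressed_tss(genes, expressed)
    classes = pd.Series("other", index=t.index, dtype=object)
    partners = pd.Series("", index=t.index, dtype=object)

    for chrom, sub in t.groupby("chrom", sort=False):
        ids = sub.index.to_numpy()
        tss = sub["tss"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        strands = sub["strand"].to_numpy()
        for i in range(len(ids)):
            dists = np.abs(tss - tss[i])
            dists[i] = np.inf
            overlap = (starts < ends[i]) & (starts[i] < ends) & (np.arange(len(ids)) != i)
            # divergent: opposite strand, no overlap, TSS within 500 bp
            cand = np.flatnonzero((dists <= divergent_max) & ~overlap & (strands != strands[i]))
            if len(cand):
                j = cand[np.argmin(dists[cand])]
                classes[ids[i]] = "divergent"
                partners[ids[i]] = ids[j]
                continue
            # convergent: overlap with TSS within 2 kb
            cand = np.flatnonzero((dists <= convergent_max) & overlap)
            if len(cand):
                j = cand[np.argmin(dists[cand])]
                classes[ids[i]] = "convergent"
                partners[ids[i]] = ids[j]
                continue
            if not overlap.any() and np.min(dists) >= separated_min:
                classes[ids[i]] = "intergenic"

    separated = nearest >= separated_min
    out = pd.DataFrame({
        "gene_id": t.index,
        "class": classes,
        "partner": partners,
        "nearest_tss_distance": nearest,
        "separated_unit": separated,
    }).set_index("gene_id")
    return out


def promoter_pair_classes(genes: GeneTable, expressed, *, divergent_max: int = 500,
                          unidirectional_min: int = 10_000) -> pd.DataFrame:
    """Assign mRNAs to divergent-promoter or unidirectional classes.

    ``divergent_mRNA_mRNA`` / ``divergent_mRNA_lncRNA``: nearest expressed
    TSS is opposite-strand and within 500 bp, partner biotype decides the
    class. ``unidirectional``: nearest TSS at least 10 kb away. Genes with a
    neighbour between the thresholds are excluded (class ``none``).
    """
    t = _tss_frame(genes, expressed)
    nearest, partner = _nearest_expressed_tss(genes, expressed)
    cls = pd.Series("none", index=t.index, dtype=object)
    for gid in t.index:
        d = nearest[gid]
        if d >= unidirectional_min:
            cls[gid] = "unidirectional"
        elif d <= divergent_max:
            p = partner[gid]
            if p and t.at[gid, "strand"] != t.at[p, "strand"]:
                pb = t.at[p, "biotype"]
                cls[gid] = (
                    "divergent_mRNA_lncRNA" if pb == "lncRNA" else "divergent_mRNA_mRNA"
                )
    return pd.DataFrame({"class": cls, "partner": partner, "nearest_tss_distance": nearest})


def expression_vs_tss_distance(genes: GeneTable, mean_expression: pd.Series,
                               window: int = 51) -> pd.DataFrame:
    """Rolling median of expression against distance to the nearest TSS.

    Genes are sorted by their distance to the nearest other gene's TSS and a
    rolling median of the given (odd) window is returned with the distance
    midpoints — the curve used to pick the separated-unit distance cutoff.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    expressed = mean_expression.index
    nearest, _ = _nearest_expressed_tss(genes, expressed)
    if len(expressed) < window:
        raise ValueError("fewer genes than the rolling window")
    order = nearest.sort_values().index
    dist = nearest[order].to_numpy()
    expr = mean_expression[order].to_numpy(dtype=float)
    med = pd.Series(expr).rolling(window, center=True).median().to_numpy()
    mid = pd.Series(dist).rolling(window, center=True).median().to_numpy()
    keep = ~np.isnan(med)
    return pd.DataFrame({"distance": mid[keep], "rolling_median": med[keep]})
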