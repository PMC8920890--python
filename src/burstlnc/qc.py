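"""Allelic UMI distribution, allelic imbalance and quality-control filters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QC_PRESETS, ConfigError
from .containers import AllelicCountSet, GeneTable

__all__ = [
    "allelic_imbalance",
    "distribute_umis",
    "distribute_umis_matrix",
    "cell_qc",
    "cell_qc_metrics",
    "gene_filter",
    "CellQCReport",
]


def allelic_imbalance(cast, c57):
    """Signed allelic skew in [-0.5, +0.5]: cast/(cast+c57) - 0.5.

    Positive values mean CAST-skewed expression. Entries with no allelic
    reads are undefined and returned as NaN.
    """
    cast = np.asarray(cast, dtype=float)
    c57 = np.asarray(c57, dtype=float)
    total = cast + c57
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, cast / np.where(total > 0, total, 1.0) - 0.5, np.nan)
    return ai if ai.ndim else float(ai)


def distribute_umis(total_umi: int, cast_reads: int, c57_reads: int):
    """Assign a total molecule count to alleles by the allele-sensitive read fraction.

    Returns ``(umi_cast, umi_c57)``; a zero total is a true zero ``(0, 0)``;
    a positive total with no allele-sensitive reads is unassignable and
    returns ``(nan, nan)``. The CAST share is rounded half-to-even and the
    remainder goes to C57, so totals are conserved exactly.
    """
    if min(total_umi, cast_reads, c57_reads) < 0:
        raise ValueError("counts must be non-negative")
    if total_umi == 0:
        return (0, 0)
    reads = cast_reads + c57_reads
    if reads == 0:
        return (np.nan, np.nan)
    umi_cast = int(np.round(total_umi * cast_reads / reads))  # numpy rounds half-to-even
    return (umi_cast, total_umi - umi_cast)


def distribute_umis_matrix(cs: AllelicCountSet) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Vectorized :func:`distribute_umis` over a count set.

    Returns ``(umi_cast, umi_c57, missing_mask)``; allele frames hold NaN
    where assignment is missing.
    """
    totals = cs.totals.to_numpy(dtype=float)
    cast = cs.cast_reads.to_numpy(dtype=float)
    c57 = cs.c57_reads.to_numpy(dtype=float)
    reads = cast + c57
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(reads > 0, cast / np.where(reads > 0, reads, 1.0), np.nan)
    umi_cast = np.round(totals * frac)
    missing = (totals > 0) & (reads == 0)
    umi_cast = np.where(totals == 0, 0.0, umi_cast)
    umi_c57 = np.where(totals == 0, 0.0, totals - umi_cast)
    umi_cast[missing] = np.nan
    umi_c57[missing] = np.nan
    idx, cols = cs.genes, cs.cells
    return (
        pd.DataFrame(umi_cast, index=idx, columns=cols),
        pd.DataFrame(umi_c57, index=idx, columns=cols),
        pd.DataFrame(missing, index=idx, columns=cols),
    )


@dataclass
class CellQCReport:
    """Per-cell QC metrics and pass/fail with enumerated reasons."""

    table: pd.DataFrame  # one row per cell

    @property
    def passing_cells(self) -> pd.Index:
        return self.table.index[self.table["pass"]]


def cell_qc_metrics(cs: AllelicCountSet, genes: GeneTable | None = None, *,
                    gene_detect_count: int = 5) -> pd.DataFrame:
    """Compute the per-cell statistics the QC presets threshold.

    The allelic-balance score is the mean, over autosomal non-imprinted genes
    with allelic reads, of the per-gene allelic imbalance in that cell. The
    imprinted-X fraction is the share of allelic reads mapped to X-linked
    genes.
    """
    totals = cs.totals
    metrics = pd.DataFrame(index=cs.cells)
    metrics["total_reads"] = totals.sum(axis=0)
    metrics["genes_detected"] = (totals >= gene_detect_count).sum(axis=0)
    if genes is not None:
        auto = genes.autosomal_non_imprinted().intersection(cs.genes)
        x_genes = genes.table.index[genes.table["x_linked"]].intersection(cs.genes)
    else:
        auto = cs.genes
        x_genes = pd.Index([])
    cast = cs.cast_reads.loc[auto].to_numpy(dtype=float)
    c57 = cs.c57_reads.loc[auto].to_numpy(dtype=float)
    ai = allelic_imbalance(cast, c57)
    with np.errstate(invalid="ignore"):
        metrics["allelic_balance"] = np.nanmean(ai, axis=0) if len(auto) else np.nan
    allelic_total = (cs.cast_reads + cs.c57_reads).sum(axis=0).astype(float)
    if len(x_genes):
        x_total = (cs.cast_reads.loc[x_genes] + cs.c57_reads.loc[x_genes]).sum(axis=0)
        metrics["imprinted_x_fraction"] = np.where(
            allelic_total > 0, x_total / allelic_total.replace(0, 1), 0.0
        )
    else:
        metrics["imprinted_x_fraction"] = 0.0
    return metrics


def cell_qc(metrics: pd.DataFrame, preset: str = "smartseq2_fibro",
            overrides: dict | None = None) -> CellQCReport:
    """Apply a named QC preset to per-cell metrics.

    Failure reasons enumerate every violated threshold; a cell passes iff it
    has none. ``overrides`` replaces individual preset thresholds (e.g. to
    rescale count-depth screens for synthetic data); preset defaults stay at
    the published values.
    """
    if preset not in QC_PRESETS:
        raise ConfigError(f"unknown QC preset {preset!r}; known: {sorted(QC_PRESETS)}")
    th = {**QC_PRESETS[preset], **(overrides or {})}
    out = metrics.copy()
    reasons = [[] for _ in range(len(out))]

    def check(col, key, kind):
        if key not in th or col not in out.columns:
            return
        v = out[col].to_numpy(dtype=float)
        if kind == "min":
            bad = v < th[key]
        else:
            bad = v > th[key]
        for i in np.flatnonzero(bad):
            reasons[i].append(col)

    check("total_reads", "min_reads", "min")
    check("exon_reads", "min_exon_reads", "min")
    check("total_umis", "min_umis", "min")
    check("genes_detected", "min_genes", "min")
    if "allelic_balance_low" in th and "allelic_balance" in out.columns:
        v = out["allelic_balance"].to_numpy(dtype=float)
        bad = ~((v > th["allelic_balance_low"]) & (v < th["allelic_balance_high"]))
        for i in np.flatnonzero(bad):
            reasons[i].append("allelic_balance")
    check("imprinted_x_fraction", "max_imprinted_x_fraction", "max")
    out["fail_reasons"] = [";".join(r) for r in reasons]
    out["pass"] = [len(r) == 0 for r in reasons]
    return CellQCReport(table=out)


def gene_filter(counts: pd.DataFrame, min_count: int = 5, min_cells: int = 2) -> pd.Index:
    """Genes with at least ``min_count`` counts in at least ``min_cells`` cells."""
    if min_count < 0 or min_cells < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (counts >= min_count).sum(axis=1) >= min_cells
    return counts.index[keep]
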