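"""Core in-memory containers shared by all pipeline stages.

The central object is :class:`AllelicCountSet`: a gene x cell matrix of total
molecule counts (UMIs or reads) together with the CAST- and C57-assigned read
counts used to distribute totals to the two parental alleles. Genomic metadata
travels in a :class:`GeneTable`. Both wrap pandas DataFrames and validate their
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AllelicCountSet",
    "GeneTable",
    "TwoStateKinetics",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class TwoStateKinetics:
    """Parameters of the two-state (telegraph) model of transcription.

    Rates are expressed in units of the mRNA degradation rate: ``k_on`` is the
    promoter activation rate (burst frequency), ``k_off`` the inactivation
    rate, and ``k_syn`` the transcription rate while the promoter is ON.
    Burst size and mean expression are derived, never stored.
    """

    k_on: float
    k_off: float
    k_syn: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_syn"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")

    @property
    def burst_size(self) -> float:
        """Mean number of RNA molecules produced per burst, k_syn / k_off."""
        return self.k_syn / self.k_off

    @property
    def mean(self) -> float:
        """Steady-state mean expression, k_syn * k_on / (k_on + k_off)."""
        return self.k_syn * self.k_on / (self.k_on + self.k_off)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_on, self.k_off, self.k_syn)


def _check_count_frame(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy()
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{name} contains non-integer counts")


@dataclass
class AllelicCountSet:
    """Gene x cell totals plus allele-assigned read counts.

    ``totals`` holds molecule counts (UMIs for Smart-seq3-like data, reads for
    read-count data). ``cast_reads`` / ``c57_reads`` hold the allele-sensitive
    read counts used to split each total between alleles. An entry with a
    positive total but no allele-sensitive reads cannot be assigned and is
    flagged in ``missing_mask``.
    """

    totals: pd.DataFrame
    cast_reads: pd.DataFrame
    c57_reads: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("totals", "cast_reads", "c57_reads"):
            df = getattr(self, name)
            if not df.index.is_unique:
                raise ValidationError(f"{name}: duplicate gene identifiers")
            if not df.columns.is_unique:
                raise ValidationError(f"{name}: duplicate cell identifiers")
        if not (
            self.totals.index.equals(self.cast_reads.index)
            and self.totals.index.equals(self.c57_reads.index)
            and self.totals.columns.equals(self.cast_reads.columns)
            and self.totals.columns.equals(self.c57_reads.columns)
        ):
            raise ValidationError("totals and allelic matrices must share gene/cell identifiers")
        for name in ("totals", "cast_reads", "c57_reads"):
            _check_count_frame(getattr(self, name), name)
        allelic = self.cast_reads.to_numpy() + self.c57_reads.to_numpy()
        if np.any(allelic > self.totals.to_numpy()):
            i, j = np.argwhere(allelic > self.totals.to_numpy())[0]
            raise ValidationError(
                "allele-assigned counts exceed totals for gene "
                f"{self.totals.index[i]!r}, cell {self.totals.columns[j]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.totals.index

    @property
    def cells(self) -> pd.Index:
        return self.totals.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a total is observed but no allele-sensitive read was captured."""
        allelic = self.cast_reads + self.c57_reads
        return (self.totals > 0) & (allelic == 0)

    def subset(self, genes=None, cells=None) -> "AllelicCountSet":
        g = self.genes if genes is None else pd.Index(genes)
        c = self.cells if cells is None else pd.Index(cells)
        return AllelicCountSet(
            totals=self.totals.loc[g, c],
            cast_reads=self.cast_reads.loc[g, c],
            c57_reads=self.c57_reads.loc[g, c],
        )


_VALID_STRANDS = {"+", "-"}

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "imprinted", "x_linked"]


@dataclass
class GeneTable:
    """Genomic metadata per gene, coordinates 0-based half-open.

    The TSS is derived from the strand: ``start`` on '+', ``end - 1`` on '-'.
    Biotypes follow Ensembl naming (protein_coding, lncRNA, pseudogene
    classes). ``imprinted`` and ``x_linked`` flags drive the eligibility
    filters used throughout the pipeline.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"GeneTable missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene identifier {dup!r}")
        bad = set(df["strand"]) - _VALID_STRANDS
        if bad:
            raise ValidationError(f"unknown strand symbol(s): {sorted(bad)}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("gene with start >= end (coordinates are 0-based half-open)")
        df = df.copy()
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        object.__setattr__(self, "table", df.set_index("gene_id", drop=False))

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def tss(self, gene_id: str) -> int:
        return int(self.table.at[gene_id, "tss"])

    def subset(self, gene_ids) -> "GeneTable":
        return GeneTable(self.table.loc[list(gene_ids)].reset_index(drop=True))

    def autosomal_non_imprinted(self) -> pd.Index:
        t = self.table
        keep = ~t["imprinted"] & ~t["x_linked"]
        return t.index[keep]
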