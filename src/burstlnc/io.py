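"""Readers and writers for the formats the pipeline touches.

Count matrices come in two flavours: MatrixMarket triplets (one ``.mtx`` per
layer, with ``genes.tsv`` / ``cells.tsv`` identifier files alongside) and wide
TSV matrices (genes as rows, cells as columns). Annotation is read from plain
TSV, BED6 or GFF3. All result tables are TSV with a ``#``-prefixed metadata
header (version, seed, config digest).
"""

from __future__ import annotations

import datetime
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import AllelicCountSet, GeneTable, ValidationError

__all__ = [
    "FormatError",
    "read_counts",
    "write_counts",
    "read_gene_table",
    "write_table",
    "read_table",
    "log",
]


class FormatError(ValueError):
    pass


_LAYERS = ("totals", "cast_reads", "c57_reads")


def log(msg: str) -> None:
    """Timestamped log line on standard error."""
    ts = datetime.datetime.now().isoformat(timespec="seconds")
    print(f"[{ts}] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"{what} identifier file not found: {path}")
    ids = [line.strip().split("\t")[0] for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers in {path}")
    return ids


def read_counts(path, format: str = "matrixmarket-triplet") -> AllelicCountSet:
    """Read an :class:`AllelicCountSet` from disk.

    ``matrixmarket-triplet``: *path* is a directory containing ``totals.mtx``,
    ``cast_reads.mtx``, ``c57_reads.mtx``, plus ``genes.tsv`` and ``cells.tsv``.
    ``wide-tsv``: *path* is a directory with ``totals.tsv``, ``cast_reads.tsv``
    and ``c57_reads.tsv`` wide matrices (genes x cells).
    """
    path = Path(path)
    if format == "matrixmarket-triplet":
        genes = _read_ids(path / "genes.tsv", "gene")
        cells = _read_ids(path / "cells.tsv", "cell")
        frames = {}
        for layer in _LAYERS:
            f = path / f"{layer}.mtx"
            if not f.exists():
                raise FileNotFoundError(f"missing layer file {f}")
            try:
                mat = scipy.io.mmread(f)
            except ValueError as exc:
                raise FormatError(f"malformed MatrixMarket header in {f}: {exc}") from exc
            arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
            if arr.shape != (len(genes), len(cells)):
                raise ValidationError(
                    f"{f}: shape {arr.shape} does not match "
                    f"{len(genes)} genes x {len(cells)} cells"
                )
            frames[layer] = pd.DataFrame(arr.astype(np.int64), index=genes, columns=cells)
        return AllelicCountSet(**frames)
    elif format == "wide-tsv":
        frames = {}
        for layer in _LAYERS:
            f = path / f"{layer}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"missing layer file {f}")
            df = pd.read_csv(f, sep="\t", index_col=0, comment="#")
            frames[layer] = df.astype(np.int64)
        return AllelicCountSet(**frames)
    raise FormatError(f"unknown counts format {format!r}")


def write_counts(cs: AllelicCountSet, path, format: str = "matrixmarket-triplet") -> None:
    """Write counts in canonical (sorted gene/cell) order; round-trips exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cs = cs.subset(genes=sorted(cs.genes), cells=sorted(cs.cells))
    if format == "matrixmarket-triplet":
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in cs.genes))
        (path / "cells.tsv").write_text("".join(f"{c}\n" for c in cs.cells))
        for layer in _LAYERS:
            mat = scipy.sparse.coo_matrix(getattr(cs, layer).to_numpy())
            scipy.io.mmwrite(path / f"{layer}.mtx", mat, field="integer")
    elif format == "wide-tsv":
        for layer in _LAYERS:
            getattr(cs, layer).to_csv(path / f"{layer}.tsv", sep="\t")
    else:
        raise FormatError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _finish_gene_frame(df: pd.DataFrame) -> GeneTable:
    for col, default in (("biotype", "protein_coding"), ("imprinted", False), ("x_linked", None)):
        if col not in df.columns:
            if col == "x_linked":
                df[col] = df["chrom"].isin(["chrX", "X"])
            else:
                df[col] = default
    df["imprinted"] = df["imprinted"].astype(bool)
    df["x_linked"] = df["x_linked"].astype(bool)
    return GeneTable(df.reset_index(drop=True))


def read_gene_table(path, format: str | None = None) -> GeneTable:
    """Read gene annotation from TSV, BED6 or GFF3.

    Coordinates are converted to the internal 0-based half-open convention:
    BED is already 0-based half-open; GFF3 is 1-based closed, so start is
    shifted down by one. The TSS is start on '+' and end-1 on '-'.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"bed": "bed6", "gff3": "gff3", "gff": "gff3", "tsv": "tsv"}.get(
            suffix.lstrip("."), "tsv"
        )
    if format == "bed6":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
        )
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    elif format == "gff3":
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        )
        raw = raw[raw["type"].isin(["gene", "ncRNA_gene", "pseudogene"])]
        ids, biotypes = [], []
        for attrs in raw["attrs"]:
            fields = dict(
                kv.split("=", 1) for kv in str(attrs).split(";") if "=" in kv
            )
            gid = fields.get("ID", fields.get("gene_id", ""))
            ids.append(gid.split(":")[-1])
            biotypes.append(fields.get("biotype", fields.get("gene_biotype", "protein_coding")))
        df = pd.DataFrame(
            {
                "gene_id": ids,
                "chrom": raw["chrom"].to_numpy(),
                "start": raw["start"].to_numpy(dtype=np.int64) - 1,  # GFF3 is 1-based
                "end": raw["end"].to_numpy(dtype=np.int64),
                "strand": raw["strand"].to_numpy(),
                "biotype": biotypes,
            }
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return _finish_gene_frame(df)


# ---------------------------------------------------------------------------
# result tables with metadata headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, *, seed: int | None = None,
                config_digest: str | None = None, stage: str | None = None) -> None:
    """Write a TSV result table with a commented metadata header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# burstlnc_version={__version__}\n")
        if stage is not None:
            fh.write(f"# stage={stage}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_digest is not None:
            fh.write(f"# config_digest={config_digest}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
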