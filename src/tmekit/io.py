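"""Readers and writers for the plain-text exchange formats.

Count matrices travel as a 10x-style triplet (matrix.mtx, features.tsv,
barcodes.tsv); cell annotations, ligand-receptor catalogues and bulk TPM
tables as TSV. Ligand/receptor complexes are semicolon-joined gene lists.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import CountMatrix

__all__ = [
    "write_10x",
    "read_10x",
    "write_cells",
    "read_cells",
    "write_lr_table",
    "read_lr_table",
    "write_bulk",
    "read_bulk",
    "read_gene_set",
]


def write_10x(counts: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(counts.matrix))
    pd.Series(counts.genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_10x(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    matrix = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return CountMatrix(genes=genes, barcodes=barcodes, matrix=matrix)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.rename_axis("barcode").to_csv(path, sep="\t")


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_lr_table(lr: pd.DataFrame, path: str | Path) -> None:
    out = lr.copy()
    out["ligand_genes"] = out["ligand_genes"].map(";".join)
    out["receptor_genes"] = out["receptor_genes"].map(";".join)
    out.to_csv(path, sep="\t", index=False)


def read_lr_table(path: str | Path) -> pd.DataFrame:
    lr = pd.read_csv(path, sep="\t")
    for col in ("ligand_genes", "receptor_genes"):
        lr[col] = lr[col].map(lambda s: tuple(str(s).split(";")))
    return lr


def write_bulk(bulk: pd.DataFrame, labels: pd.Series, prefix: str | Path) -> None:
    prefix = Path(prefix)
    bulk.rename_axis("gene").to_csv(prefix.with_suffix(".tsv"), sep="\t")
    labels.rename("condition").rename_axis("sample").to_csv(
        prefix.with_name(prefix.name + "_labels.tsv"), sep="\t"
    )


def read_bulk(prefix: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    prefix = Path(prefix)
    bulk = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="gene")
    labels = pd.read_csv(
        prefix.with_name(prefix.name + "_labels.tsv"), sep="\t", index_col="sample"
    )["condition"]
    return bulk, labels


def read_gene_set(path: str | Path) -> tuple[str, list[str]]:
    """One-gene-per-line text file whose first line is the set name."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty gene-set file {path}")
    return lines[0], lines[1:]
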