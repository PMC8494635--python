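"""Reading and writing count matrices and annotation tables.

Two dialects are supported: MatrixMarket coordinate files with sibling
gene/barcode TSVs (the 10x-style triplet, genes as rows), and a dense TSV
with a header row of cell ids and a first column of gene ids for toy data.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import ANNOTATION_COLUMNS, CellAnnotation, ExpressionMatrix, ValidationError


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


def _read_id_column(path: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_expression(
    path_matrix: str,
    path_genes: str | None = None,
    path_cells: str | None = None,
    cells_are_rows: bool = False,
) -> ExpressionMatrix:
    """Read a count matrix from MTX + id TSVs or from a dense TSV.

    If ``path_genes``/``path_cells`` are given, ``path_matrix`` is parsed as
    MatrixMarket coordinate format and kept sparse.  Otherwise it is read as
    a dense TSV (header = cell ids, first column = gene ids); set
    ``cells_are_rows`` if the toy table is transposed.
    """
    if (path_genes is None) != (path_cells is None):
        raise FormatError("provide both gene and cell id files, or neither")
    if path_genes is not None:
        try:
            mat = scipy.io.mmread(path_matrix)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise FormatError(f"cannot parse MatrixMarket file {path_matrix}: {exc}") from exc
        genes = _read_id_column(path_genes)
        cells = _read_id_column(path_cells)
        if mat.shape[0] != len(genes):
            raise FormatError(
                f"{path_genes} has {len(genes)} rows but matrix declares {mat.shape[0]} genes"
            )
        if mat.shape[1] != len(cells):
            raise FormatError(
                f"{path_cells} has {len(cells)} rows but matrix declares {mat.shape[1]} cells"
            )
        return ExpressionMatrix(sp.csr_matrix(mat), genes, cells)

    df = pd.read_csv(path_matrix, sep="\t", index_col=0)
    if cells_are_rows:
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(), df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)
    )


def write_expression(expr: ExpressionMatrix, path_matrix: str,
                     path_genes: str | None = None, path_cells: str | None = None) -> None:
    """Write MTX + id TSVs when id paths are given, else a dense TSV."""
    if (path_genes is None) != (path_cells is None):
        raise FormatError("provide both gene and cell id paths, or neither")
    if path_genes is not None:
        vals = expr.values if sp.issparse(expr.values) else sp.coo_matrix(expr.values)
        scipy.io.mmwrite(path_matrix, vals.astype(int))
        # mmwrite appends .mtx if missing; normalise so round-trips find the file
        if not os.path.exists(path_matrix) and os.path.exists(path_matrix + ".mtx"):
            os.replace(path_matrix + ".mtx", path_matrix)
        pd.Series(expr.gene_ids).to_csv(path_genes, sep="\t", header=False, index=False)
        pd.Series(expr.cell_ids).to_csv(path_cells, sep="\t", header=False, index=False)
    else:
        pd.DataFrame(expr.dense(), index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            path_matrix, sep="\t"
        )


def read_annotation(path: str) -> CellAnnotation:
    """Read a per-cell annotation TSV with the required label columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing required columns: {missing}")
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def write_result_table(df: pd.DataFrame, path: str, *, seed=None, params: dict | None = None,
                       version: str | None = None) -> None:
    """Write a results TSV with a provenance comment header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# cerebstat {version or __version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def filter_min_umi(expr: ExpressionMatrix, min_umis: int = 500) -> ExpressionMatrix:
    """Optional QC: drop cells with fewer than ``min_umis`` total counts."""
    keep = expr.cell_totals() >= min_umis
    if not keep.any():
        raise ValidationError(f"no cells with at least {min_umis} UMIs")
    return expr.subset_cells(keep)
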