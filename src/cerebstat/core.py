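"""Core data containers and shared statistical utilities.

The package works on a genes x cells count matrix plus a per-cell annotation
table.  Counts are held sparse (CSR) whenever they arrive sparse; nothing in
the downstream stages requires densification of the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "CellAnnotation",
    "ValidationError",
    "normalize_counts",
    "bh_adjust",
]

ANNOTATION_COLUMNS = ("cell_id", "cluster", "outer_type", "lobule", "replicate")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValidationError(f"{what} are not unique")


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative integer UMI counts.

    ``values`` may be a dense ndarray or any scipy.sparse matrix; it is stored
    as CSR when sparse.  Gene and cell identifiers are unique strings aligned
    to the rows and columns respectively.
    """

    values: object
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            data = self.values.data
        else:
            self.values = np.asarray(self.values)
            data = self.values.ravel()
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if data.size and data.min() < 0:
            raise ValidationError("negative entries in count matrix")
        if data.size and np.any(data != np.round(data)):
            raise ValidationError("non-integer entries in count matrix")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def cell_totals(self) -> np.ndarray:
        """Total UMI count per cell."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _cell_index(self.cell_ids, mask_or_ids)
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])


@dataclass
class NormalizedMatrix:
    """Genes x cells per-cell depth-normalized expression.

    Produced by :func:`normalize_counts`; every column sums to the scale
    factor recorded in ``normalization_record``.
    """

    values: object
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization_record: str = "unspecified"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("matrix shape does not match id vectors")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def subset_cells(self, mask_or_ids) -> "NormalizedMatrix":
        idx = _cell_index(self.cell_ids, mask_or_ids)
        return NormalizedMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx], self.normalization_record
        )


def _cell_index(cell_ids: np.ndarray, mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != cell_ids.shape:
            raise ValidationError("boolean mask length does not match cell count")
        return np.flatnonzero(arr)
    pos = {c: i for i, c in enumerate(cell_ids)}
    try:
        return np.array([pos[c] for c in arr], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"unknown cell id {exc.args[0]!r}") from None


@dataclass
class CellAnnotation:
    """Per-cell labels: cluster, outer cell type, lobule/region, replicate.

    Every cluster must map to exactly one outer type (clusters are the fine
    partition nested inside coarse cell classes).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in annotation table")
        outer_per_cluster = self.table.groupby("cluster", observed=True)["outer_type"].nunique()
        bad = outer_per_cluster[outer_per_cluster > 1]
        if len(bad):
            raise ValidationError(
                f"clusters mapping to multiple outer types: {list(bad.index)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()

    def validate_against(self, expr) -> None:
        known = set(expr.cell_ids)
        unknown = [c for c in self.cell_ids if c not in known]
        if unknown:
            raise ValidationError(
                f"{len(unknown)} annotated cells absent from matrix, e.g. {unknown[:3]}"
            )

    def subset(self, mask) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[np.asarray(mask)].reset_index(drop=True))


def normalize_counts(expr: ExpressionMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize each cell so its expression sums to ``scale``.

    Cells with zero total counts cannot be normalized and are rejected with
    an error listing their ids.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    totals = expr.cell_totals().astype(float)
    zero = totals == 0
    if zero.any():
        raise ValidationError(
            f"cells with zero total counts: {list(expr.cell_ids[zero][:10])}"
        )
    factors = scale / totals
    if sp.issparse(expr.values):
        vals = expr.values.astype(float) @ sp.diags(factors)
        vals = sp.csr_matrix(vals)
    else:
        vals = expr.values.astype(float) * factors[np.newaxis, :]
    return NormalizedMatrix(
        vals, expr.gene_ids, expr.cell_ids, normalization_record=f"per-cell depth, scale={scale:g}"
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * n / j, capped at 1, returned in the
    input order.  NaN or out-of-range values are rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1] with no NaN")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
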