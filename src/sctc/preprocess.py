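"""Preprocessing: mitochondrial filtering, empty-row/column removal,
normalization and log transform.

The complexity core expects a clean weighted matrix: non-negative, no
all-zero cells or genes.  The canonical order is mitochondrial filter →
empty filter → normalization, matching the usual scRNA-seq QC workflow.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .matrix import EmptyResultError, ExpressionMatrix, ValidationError

__all__ = ["filter_mito", "filter_empty", "normalize_and_log", "preprocess"]


def filter_mito(
    matrix: ExpressionMatrix,
    mito_gene_flags,
    max_fraction: float = 0.15,
) -> ExpressionMatrix:
    """Remove high-mitochondrial cells and drop mitochondrial genes.

    A cell is removed when its mitochondrial fraction (sum of expression over
    flagged genes divided by total expression) is strictly greater than
    ``max_fraction``.  All flagged genes are removed from the result.  Flags
    are caller-supplied (e.g. from a name-prefix match) because gene naming
    conventions are species-specific.
    """
    flags = np.asarray(mito_gene_flags, dtype=bool)
    if flags.shape != (matrix.n_genes,):
        raise ValidationError(
            f"mito_gene_flags length {flags.size} does not match {matrix.n_genes} genes"
        )
    if not 0.0 <= max_fraction <= 1.0:
        raise ValidationError(f"max_fraction must be in [0, 1], got {max_fraction}")
    if not flags.any():
        return matrix.copy()
    totals = matrix.row_sums()
    mito = np.asarray(matrix.values[:, flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1.0), 0.0)
    keep_cells = frac <= max_fraction
    if not keep_cells.any():
        raise EmptyResultError("mitochondrial filter removed every cell")
    return matrix.subset(cell_mask=keep_cells, gene_mask=~flags)


def filter_empty(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop all-zero cells and all-zero genes until none remain.

    Removing a zero gene cannot create a zero cell (column removal does not
    change which rows are zero once zero rows are gone, and vice versa), so
    one simultaneous pass reaches the fixed point; idempotence is asserted
    in tests against a loop-until-stable oracle.
    """
    keep_cells = matrix.row_sums() > 0
    keep_genes = matrix.col_sums() > 0
    if not keep_cells.any() or not keep_genes.any():
        raise EmptyResultError("matrix has no expressed entries")
    if keep_cells.all() and keep_genes.all():
        return matrix.copy()
    return matrix.subset(cell_mask=keep_cells, gene_mask=keep_genes)


def normalize_and_log(
    matrix: ExpressionMatrix,
    target_sum: Union[float, str] = "median",
    base: float = 2.0,
) -> ExpressionMatrix:
    """Scale each cell to a common total, then log-transform.

    Each cell's counts are scaled so its total equals ``target_sum`` (the
    median of the pre-normalization totals when ``"median"``), then every
    entry ``x`` becomes ``log_base(1 + x)``.  Zeros stay zero, so the
    support pattern of the matrix is preserved exactly.

    ``base`` defaults to 2; natural log (``base=np.e``) is also accepted.
    Any fixed base is a monotone transform of any other, so rank-based
    downstream results do not depend on it.
    """
    totals = matrix.row_sums()
    if (totals <= 0).any():
        raise ValidationError("normalize_and_log requires no all-zero cells; run filter_empty first")
    if isinstance(target_sum, str):
        if target_sum != "median":
            raise ValidationError(f"target_sum must be positive or 'median', got {target_sum!r}")
        target = float(np.median(totals))
    else:
        target = float(target_sum)
    if target <= 0:
        raise ValidationError(f"target_sum must be positive, got {target}")
    if base <= 0 or base == 1:
        raise ValidationError(f"log base must be positive and != 1, got {base}")

    out = matrix.values.copy().tocsr()
    scale = target / totals
    # scale rows, then log1p on stored entries only — zeros map to zeros
    out = out.multiply(scale[:, None]).tocsr()
    out.data = np.log1p(out.data) / np.log(base)
    return ExpressionMatrix(out, matrix.cell_ids, matrix.gene_ids, matrix.stage_labels)


def preprocess(
    matrix: ExpressionMatrix,
    mito_gene_flags=None,
    max_mito_fraction: float = 0.15,
    target_sum: Union[float, str] = "median",
    base: float = 2.0,
    log: bool = True,
) -> ExpressionMatrix:
    """Full pipeline: mito filter → empty filter → normalize(+log)."""
    if mito_gene_flags is not None:
        matrix = filter_mito(matrix, mito_gene_flags, max_mito_fraction)
    matrix = filter_empty(matrix)
    if log:
        matrix = normalize_and_log(matrix, target_sum=target_sum, base=base)
    return matrix
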