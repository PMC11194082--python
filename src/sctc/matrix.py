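"""Core container for a weighted cells x genes expression matrix.

The expression matrix ``M`` is treated throughout the package as the
weighted adjacency matrix of a bipartite network: cells and genes are the
two node classes and ``M[c, g]`` is the weight of the edge between cell
``c`` and gene ``g`` (its expression level).  Everything downstream —
diversity/ubiquity, the method of reflections, the analytic complexity
indices, the RCA gene space — consumes this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "SctcError", "ValidationError", "EmptyResultError", "DegeneracyError"]


class SctcError(Exception):
    """Base class for package errors."""


class ValidationError(SctcError, ValueError):
    """Malformed or inconsistent input (misaligned labels, bad parameters)."""


class EmptyResultError(SctcError, ValueError):
    """A filter removed every cell or every gene."""


class DegeneracyError(SctcError, ArithmeticError):
    """A quantity is undefined because the input is degenerate (constant
    vectors, repeated eigenvalues, disconnected networks)."""


def _as_csr(values) -> sp.csr_matrix:
    if sp.issparse(values):
        m = values.tocsr().astype(np.float64)
    else:
        m = sp.csr_matrix(np.asarray(values, dtype=np.float64))
    m.eliminate_zeros()
    return m


@dataclass
class ExpressionMatrix:
    """Weighted cells x genes matrix with aligned identifiers.

    Parameters
    ----------
    values
        Non-negative matrix, cells as rows and genes as columns.  Stored
        internally as CSR sparse regardless of the input container.
    cell_ids, gene_ids
        Unique ordered labels; default to ``cell0..`` / ``gene0..``.
    stage_labels
        Optional per-cell categorical (time point / developmental stage),
        carried through every filter so evaluation stays aligned.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    stage_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = _as_csr(self.values)
        n_cells, n_genes = self.values.shape
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(n_cells)], dtype=object)
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{j}" for j in range(n_genes)], dtype=object)
        else:
            self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.stage_labels is not None:
            self.stage_labels = np.asarray(self.stage_labels, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"cell_ids length {len(self.cell_ids)} != number of rows {n_cells}"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != number of columns {n_genes}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene_ids")
        if self.stage_labels is not None and len(self.stage_labels) != n_cells:
            raise ValidationError(
                f"stage_labels length {len(self.stage_labels)} != number of cells {n_cells}"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("expression matrix has negative entries")

    # -- basic views ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def col_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.cell_ids.copy(),
            self.gene_ids.copy(),
            None if self.stage_labels is None else self.stage_labels.copy(),
        )

    # -- subsetting (labels follow automatically) ----------------------
    def subset(self, cell_mask=None, gene_mask=None) -> "ExpressionMatrix":
        values = self.values
        cell_ids = self.cell_ids
        gene_ids = self.gene_ids
        stages = self.stage_labels
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            values = values[cell_mask]
            cell_ids = cell_ids[cell_mask]
            if stages is not None:
                stages = stages[cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            values = values[:, gene_mask]
            gene_ids = gene_ids[gene_mask]
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise EmptyResultError("filtering removed every cell or every gene")
        return ExpressionMatrix(values, cell_ids, gene_ids, stages)

    def binarize(self, threshold: float = 0.0) -> "ExpressionMatrix":
        """Replace weights by 0/1 indicators of expression above *threshold*.

        Reproduces the count interpretation of diversity/ubiquity (number of
        genes expressed / number of cells expressing).
        """
        out = self.values.copy()
        out.data = (out.data > threshold).astype(np.float64)
        out.eliminate_zeros()
        return ExpressionMatrix(out, self.cell_ids, self.gene_ids, self.stage_labels)

    # -- interop -------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id"))
        if self.stage_labels is not None:
            obs["stage"] = self.stage_labels.astype(str)
        var = pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id"))
        return ad.AnnData(X=self.values.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata, stage_key: Optional[str] = None) -> "ExpressionMatrix":
        X = adata.X
        stages = None
        if stage_key is not None:
            if stage_key not in adata.obs:
                raise ValidationError(f"stage key {stage_key!r} not in obs")
            stages = adata.obs[stage_key].to_numpy()
        elif "stage" in adata.obs:
            stages = adata.obs["stage"].to_numpy()
        return cls(X, adata.obs_names.to_numpy(), adata.var_names.to_numpy(), stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.cell_ids, columns=self.gene_ids)
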