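"""Reading and writing expression matrices in the common single-cell formats.

Supported on disk: Matrix Market triplets with barcode/feature sidecars
(the CellRanger-style layout), dense CSV/TSV with an orientation flag, and
h5ad (AnnData).  In memory everything is a cells x genes
:class:`~sctc.matrix.ExpressionMatrix`; MTX keeps its native genes-as-rows,
1-based convention on disk.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import ExpressionMatrix, ValidationError

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels", "sniff_format"]


def sniff_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix in (".h5ad", ".h5"):
        return "h5ad"
    raise ValidationError(f"cannot infer format from {path!r}; pass input_format explicitly")


def _read_sidecar(path: Path) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy(dtype=object)
    return ids


def read_matrix(
    path: str | Path,
    input_format: Optional[str] = None,
    cells_as: str = "rows",
    barcodes: Optional[str | Path] = None,
    features: Optional[str | Path] = None,
    stage_key: Optional[str] = None,
) -> ExpressionMatrix:
    """Load an expression matrix, oriented cells x genes.

    MTX files follow the genome-toolkit convention of genes as rows on
    disk (``cells_as`` is ignored for MTX); sidecar files default to
    ``barcodes.tsv`` / ``features.tsv`` next to the matrix.  CSV/TSV obey
    ``cells_as`` ("rows" or "cols"); the header row and first column carry
    gene/cell identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    fmt = input_format or sniff_format(path)

    if fmt == "mtx":
        values = sp.csr_matrix(scipy.io.mmread(path))  # genes x cells on disk
        barcodes = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        features = Path(features) if features else path.parent / "features.tsv"
        if not barcodes.exists() or not features.exists():
            raise ValidationError(
                f"MTX sidecars not found (expected {barcodes} and {features})"
            )
        gene_ids = _read_sidecar(features)
        cell_ids = _read_sidecar(barcodes)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {len(gene_ids)} features "
                f"x {len(cell_ids)} barcodes"
            )
        return ExpressionMatrix(values.T.tocsr(), cell_ids, gene_ids)

    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValidationError(f"duplicate column identifiers in {path}")
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if frame.index.duplicated().any():
            raise ValidationError(f"duplicate row identifiers in {path}")
        if cells_as == "cols":
            frame = frame.T
        elif cells_as != "rows":
            raise ValidationError(f"cells_as must be 'rows' or 'cols', got {cells_as!r}")
        return ExpressionMatrix(
            sp.csr_matrix(frame.to_numpy(dtype=float)),
            frame.index.to_numpy(dtype=object),
            frame.columns.to_numpy(dtype=object),
        )

    if fmt == "h5ad":
        import anndata as ad

        return ExpressionMatrix.from_anndata(ad.read_h5ad(path), stage_key=stage_key)

    raise ValidationError(f"unsupported input format {fmt!r}")


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    output_format: Optional[str] = None,
    cells_as: str = "rows",
) -> None:
    """Write a matrix back out; formats mirror :func:`read_matrix`."""
    path = Path(path)
    fmt = output_format or sniff_format(path)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(matrix.values.T))
        pd.Series(matrix.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
        pd.Series(matrix.gene_ids).to_csv(path.parent / "features.tsv", sep="\t",
                                          header=False, index=False)
    elif fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        frame = matrix.to_frame()
        if cells_as == "cols":
            frame = frame.T
        frame.to_csv(path, sep=sep)
    elif fmt == "h5ad":
        matrix.to_anndata().write_h5ad(path)
    else:
        raise ValidationError(f"unsupported output format {fmt!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, stage) CSV into a Series indexed by cell."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValidationError("labels file needs two columns: cell_id, stage")
    return pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].astype(str))


def write_labels(cell_ids: Sequence, stages: Sequence, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "stage": stages}).to_csv(path, index=False)
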