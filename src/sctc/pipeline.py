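"""End-to-end pipeline with a reproducibility manifest."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import complexity as cx
from .io import read_matrix, write_labels
from .matrix import ExpressionMatrix, SctcError
from .preprocess import preprocess

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable into the manifest."""

    input_path: str
    input_format: Optional[str] = None  # mtx | csv | h5ad (None: infer)
    cells_as: str = "rows"
    max_mito_fraction: float = 0.15
    mito_prefix: Optional[str] = None  # e.g. "MT-"; None disables the filter
    target_sum: object = "median"
    log_base: float = 2.0
    log_transform: bool = True
    binarize: bool = False
    seed: int = 0
    out_dir: str = "sctc_out"


def _file_sha1(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """preprocess → complexity indices → pseudotime, with artifacts + manifest.

    Writes ``indices.csv`` (cell_id, cci, pseudotime), ``genes.csv``
    (gene_id, gci) and ``manifest.json`` into ``config.out_dir``.  Returns
    the manifest.  Any stage failure removes partial outputs and re-raises
    with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    try:
        matrix = read_matrix(config.input_path, config.input_format, cells_as=config.cells_as)

        stage = "preprocess"
        flags = None
        if config.mito_prefix:
            flags = np.array(
                [str(g).upper().startswith(config.mito_prefix.upper()) for g in matrix.gene_ids]
            )
        matrix = preprocess(
            matrix,
            mito_gene_flags=flags,
            max_mito_fraction=config.max_mito_fraction,
            target_sum=config.target_sum,
            base=config.log_base,
            log=config.log_transform,
        )
        if config.binarize:
            matrix = matrix.binarize()

        stage = "complexity"
        indices = cx.analytic_cci(matrix, seed=config.seed)
        indices = cx.gci_from_cci(matrix, indices)
        pt = cx.pseudotime(indices)

        stage = "write"
        idx_path = out / "indices.csv"
        pd.DataFrame(
            {"cell_id": matrix.cell_ids, "cci": indices.cci, "pseudotime": pt}
        ).to_csv(idx_path, index=False)
        written.append(idx_path)
        gene_path = out / "genes.csv"
        pd.DataFrame({"gene_id": matrix.gene_ids, "gci": indices.gci}).to_csv(
            gene_path, index=False
        )
        written.append(gene_path)

        manifest = {
            "version": __version__,
            "input": str(config.input_path),
            "input_sha1": _file_sha1(config.input_path),
            "parameters": {k: v for k, v in asdict(config).items() if k != "input_path"},
            "seed": config.seed,
            "n_cells": matrix.n_cells,
            "n_genes": matrix.n_genes,
            "second_eigenvalue": indices.second_eigenvalue,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str))
        written.append(man_path)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise SctcError(f"pipeline failed at stage {stage!r}: {exc}") from exc
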