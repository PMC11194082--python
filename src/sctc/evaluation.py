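"""Scoring pseudotime orderings and robustness protocols.

Accuracy is the Spearman correlation (SCC) between a pseudotime vector and
integer-coded developmental stage labels; cluster separation of stages
along a one-dimensional complexity feature is measured with the Silhouette
coefficient.  Dropout robustness re-runs the full pipeline on matrices with
nonzero entries zeroed independently at a given rate.  All functions leave
their input matrix untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import silhouette_score

from . import complexity as cx
from .matrix import DegeneracyError, ExpressionMatrix, EmptyResultError, ValidationError
from .preprocess import filter_empty

__all__ = [
    "EvaluationReport",
    "encode_stages",
    "scc_vs_labels",
    "diversity_baseline",
    "mean_gene_complexity",
    "silhouette_over_orders",
    "rank_genes_by_metric",
    "marker_stage_concordance",
    "find_stage_markers",
    "dropout_simulate",
    "robustness_curve",
]


@dataclass
class EvaluationReport:
    """Bundle of evaluation outputs, keyed the way the protocols produce them."""

    scc_by_method: Dict[str, float] = field(default_factory=dict)
    silhouette_by_order: Dict[int, float] = field(default_factory=dict)
    marker_rankings: Dict[str, pd.DataFrame] = field(default_factory=dict)
    diagram_points: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "scc_by_method": self.scc_by_method,
            "silhouette_by_order": {str(k): v for k, v in self.silhouette_by_order.items()},
        }
        if self.marker_rankings:
            out["marker_rankings"] = {
                k: v.to_dict(orient="list") for k, v in self.marker_rankings.items()
            }
        return out


def encode_stages(stage_labels: Sequence, stage_order: Optional[Sequence] = None) -> np.ndarray:
    """Map categorical stage labels to integer codes 0..K-1.

    Order comes from ``stage_order`` when given; otherwise from the sorted
    unique labels.  The order is never inferred from label text beyond that.
    """
    labels = np.asarray(stage_labels)
    if stage_order is None:
        stage_order = sorted(set(labels.tolist()))
    lut = {s: i for i, s in enumerate(stage_order)}
    missing = set(labels.tolist()) - set(lut)
    if missing:
        raise ValidationError(f"labels not in stage_order: {sorted(missing)!r}")
    return np.array([lut[s] for s in labels], dtype=int)


def scc_vs_labels(
    scores: np.ndarray,
    stage_labels: Sequence,
    stage_order: Optional[Sequence] = None,
) -> float:
    """Spearman correlation between a score vector and stage order."""
    scores = np.asarray(scores, dtype=float)
    codes = encode_stages(stage_labels, stage_order)
    if len(scores) != len(codes):
        raise ValidationError(f"{len(scores)} scores vs {len(codes)} labels")
    if len(np.unique(codes)) < 2:
        raise DegeneracyError("correlation undefined with a single stage")
    return float(spearmanr(scores, codes).statistic)


def diversity_baseline(matrix: ExpressionMatrix, normalize: bool = True) -> np.ndarray:
    """Number of expressed genes per cell (transcriptional diversity).

    This is the core assumption of gene-count-based potency scores: more
    expressed genes, higher potential.  Min-max normalized by default so
    ``1 - diversity_baseline(m)`` is a pseudotime on the same [0,1] scale
    as the complexity-based one.  This is a plain diversity ranking, not a
    reimplementation of any published potency tool.
    """
    counts = np.asarray((matrix.values > 0).sum(axis=1)).ravel().astype(float)
    if not normalize:
        return counts
    return cx.minmax(counts)


def mean_gene_complexity(
    matrix: ExpressionMatrix,
    gene_values: np.ndarray,
) -> np.ndarray:
    """Per-cell unweighted mean of a gene-level score over expressed genes."""
    gene_values = np.asarray(gene_values, dtype=float)
    if gene_values.shape != (matrix.n_genes,):
        raise ValidationError("gene score length does not match gene count")
    support = matrix.values.copy()
    support.data = np.ones_like(support.data)
    counts = np.asarray(support.sum(axis=1)).ravel()
    if (counts == 0).any():
        raise ValidationError("cells with no expressed genes; run filter_empty")
    return np.asarray(support @ gene_values).ravel() / counts


def silhouette_over_orders(
    table: cx.ComplexityTable,
    matrix: ExpressionMatrix,
    stage_labels: Sequence,
    orders: Optional[Sequence[int]] = None,
    stage_order: Optional[Sequence] = None,
    use_ranks: bool = False,
) -> Dict[int, float]:
    """Silhouette of stage clusters along 1-D mean gene complexity, per order.

    For each odd order N the feature is the per-cell mean of gene column N
    over expressed genes; N=0 is the diversity baseline (expressed-gene
    count).  The silhouette is computed on the feature values themselves;
    with ``use_ranks=True`` it is computed on their ranks instead, which
    makes the statistic invariant to any strictly monotone rescaling of the
    feature (value-scale silhouette is not, being distance-based).  Stages
    with a single cell are excluded with a warning, since a singleton
    cluster has no silhouette.
    """
    if orders is None:
        orders = [0] + [N for N in range(1, table.N_max + 1, 2)]
    codes = encode_stages(np.asarray(stage_labels), stage_order)
    out: Dict[int, float] = {}

    uniq, counts = np.unique(codes, return_counts=True)
    ok_stages = uniq[counts > 1]
    if len(ok_stages) < len(uniq):
        warnings.warn("excluding singleton stages from silhouette", stacklevel=2)
    keep = np.isin(codes, ok_stages)
    if len(np.unique(codes[keep])) < 2:
        raise DegeneracyError("need at least two stages with >= 2 cells")

    for N in orders:
        if N == 0:
            feature = diversity_baseline(matrix, normalize=False)
        else:
            if N > table.N_max:
                raise ValidationError(f"order {N} exceeds table N_max={table.N_max}")
            feature = mean_gene_complexity(matrix, table.gene_complexity[:, N])
        feature = feature[keep]
        if use_ranks:
            feature = rankdata(feature)
        out[int(N)] = float(silhouette_score(feature.reshape(-1, 1), codes[keep]))
    return out


def rank_genes_by_metric(
    gene_ids: Sequence,
    metric_values: np.ndarray,
) -> pd.DataFrame:
    """Genes sorted by a complexity metric, highest first; stable under ties."""
    metric_values = np.asarray(metric_values, dtype=float)
    order = np.argsort(-metric_values, kind="stable")
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object)[order],
            "value": metric_values[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def find_stage_markers(
    matrix: ExpressionMatrix,
    stage_labels: Sequence,
    top_n: int = 10,
) -> Dict[object, List[str]]:
    """Top differentially-expressed genes per stage (Wilcoxon rank-sum).

    Convenience wrapper around scanpy's one-vs-rest ranking; approximate in
    the sense that any marker caller would be — the concordance protocol
    accepts an external marker table just as readily.
    """
    import scanpy as sc

    adata = matrix.to_anndata()
    adata.obs["stage"] = pd.Categorical([str(s) for s in np.asarray(stage_labels)])
    sc.tl.rank_genes_groups(adata, "stage", method="wilcoxon", n_genes=top_n)
    names = adata.uns["rank_genes_groups"]["names"]
    return {stage: [str(g) for g in names[stage]] for stage in names.dtype.names}


def marker_stage_concordance(
    marker_table: Dict[object, Sequence[str]],
    ranking: pd.DataFrame,
    stage_order: Sequence,
) -> float:
    """SCC between marker genes' complexity ranks and their stages' order.

    Early stages should hold the top (smallest) ranks in a complexity-based
    gene ranking, so concordance is the Spearman correlation between rank
    position and stage index — positive when early markers rank high.
    Markers absent from the ranking are excluded with a warning.
    """
    pos = {g: r for g, r in zip(ranking["gene"], ranking["rank"])}
    xs: List[float] = []
    ys: List[int] = []
    for s_idx, stage in enumerate(stage_order):
        for g in marker_table.get(stage, []):
            if g in pos:
                xs.append(pos[g])
                ys.append(s_idx)
            else:
                warnings.warn(f"marker {g!r} absent from ranking; excluded", stacklevel=2)
    if len(set(ys)) < 2:
        raise DegeneracyError("need markers from at least two stages")
    return float(spearmanr(xs, ys).statistic)


def dropout_simulate(
    matrix: ExpressionMatrix,
    rate: float,
    seed: int,
) -> ExpressionMatrix:
    """Zero each nonzero entry independently with probability ``rate``,
    then drop cells/genes left empty.  Fully determined by ``seed``."""
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"dropout rate must be in [0, 1], got {rate}")
    out = matrix.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        keep = rng.random(out.values.nnz) >= rate
        out.values.data = out.values.data * keep
        out.values.eliminate_zeros()
    return filter_empty(out)


def robustness_curve(
    matrix: ExpressionMatrix,
    stage_labels: Sequence,
    rates: Sequence[float],
    repeats: int = 10,
    seed: int = 0,
    stage_order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Mean ± sd pseudotime accuracy under dropout, for SCTC and the
    diversity baseline.

    For every (rate, repeat) pair: simulate dropout, recompute both
    pseudotimes on the surviving matrix, and score each against the
    surviving stage labels.  Returns a tidy frame with columns
    (rate, method, mean_scc, sd_scc, n_repeats).
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    labels = np.asarray(stage_labels, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValidationError("stage labels misaligned with matrix")
    base = ExpressionMatrix(matrix.values.copy(), matrix.cell_ids, matrix.gene_ids, labels)

    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(rates) * repeats)]

    rows = []
    k = 0
    for rate in rates:
        scores: Dict[str, List[float]] = {"sctc": [], "diversity": []}
        for _ in range(repeats):
            dropped = dropout_simulate(base, rate, seed=sub_seeds[k])
            k += 1
            idx = cx.analytic_cci(dropped)
            pt_sctc = cx.pseudotime(idx)
            pt_div = 1.0 - diversity_baseline(dropped)
            scores["sctc"].append(
                scc_vs_labels(pt_sctc, dropped.stage_labels, stage_order)
            )
            scores["diversity"].append(
                scc_vs_labels(pt_div, dropped.stage_labels, stage_order)
            )
        for method, vals in scores.items():
            rows.append(
                {
                    "rate": rate,
                    "method": method,
                    "mean_scc": float(np.mean(vals)),
                    "sd_scc": float(np.std(vals, ddof=0)),
                    "n_repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
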