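"""The gene space: RCA, proximity, and its maximum spanning tree.

Borrowing the product-space construction from economic complexity, a cell
"significantly" expresses a gene when its Revealed Comparative Advantage

    RCA_cg = (x_cg / sum_g x_cg) / (sum_c x_cg / sum_cg x_cg)

is at least 1, i.e. the gene takes a larger share of that cell's output
than of the global output.  The proximity between genes i and j is the
minimum of the two conditional probabilities that a cell significantly
expressing one also significantly expresses the other; the proximity matrix
is the adjacency matrix of the gene-gene network, summarized by its maximum
spanning tree.  Genes sitting in the densely-connected core of this network
are the ones high-complexity (early, high-potential) cells express.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .matrix import ExpressionMatrix, ValidationError

__all__ = ["RcaMatrix", "GeneSpace", "rca", "proximity", "maximum_spanning_tree",
           "gene_degrees", "mean_expressed_degree", "build_gene_space"]


@dataclass
class RcaMatrix:
    """Cells x genes revealed-comparative-advantage matrix."""

    values: np.ndarray
    threshold: float = 1.0
    cell_ids: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None

    def advantage(self) -> np.ndarray:
        """Boolean cells x genes matrix of RCA >= threshold."""
        return self.values >= self.threshold


@dataclass
class GeneSpace:
    """Gene-gene proximity network and derived structures."""

    proximity: np.ndarray
    gene_ids: Optional[np.ndarray] = None
    mst_edges: Optional[List[Tuple[int, int, float]]] = None
    degree: Optional[np.ndarray] = None
    never_advantaged: Optional[np.ndarray] = None  # genes with no RCA>=th cell


def rca(matrix: ExpressionMatrix) -> RcaMatrix:
    """Revealed comparative advantage of each gene in each cell.

    Entry (c, g) is the cell's expression share of gene g divided by the
    global share of gene g.  Per-cell the expression-share-weighted mean of
    RCA is identically 1.  Genes with zero total yield RCA 0 by convention.
    """
    X = matrix.values.toarray()
    grand = X.sum()
    if grand <= 0:
        raise ValidationError("RCA undefined for an all-zero matrix")
    cell_tot = X.sum(axis=1, keepdims=True)
    gene_tot = X.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        share_cell = np.where(cell_tot > 0, X / cell_tot, 0.0)
        share_gene = np.where(gene_tot > 0, gene_tot / grand, np.inf)
        out = np.where(gene_tot > 0, share_cell / share_gene, 0.0)
    return RcaMatrix(values=out, cell_ids=matrix.cell_ids, gene_ids=matrix.gene_ids)


def proximity(rca_matrix: RcaMatrix) -> GeneSpace:
    """Pairwise gene proximity: min of the two conditional co-advantage
    probabilities P(i|j) = #{cells advantaged in both} / #{cells advantaged in j}.

    min(C_ij/n_i, C_ij/n_j) = C_ij / max(n_i, n_j).  Genes advantaged in no
    cell have undefined conditionals (0/0); they get proximity 0 to every
    gene including themselves and are flagged, not fatal.
    """
    A = rca_matrix.advantage().astype(np.float64)
    if not A.any():
        raise ValidationError("no cell reaches the RCA threshold anywhere")
    C = A.T @ A  # co-advantage counts; diagonal = per-gene counts
    n = np.diag(C).copy()
    never = n == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} genes are never advantaged (RCA < threshold in "
            "every cell); their proximity is set to 0",
            stacklevel=2,
        )
    denom = np.maximum.outer(n, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, C / denom, 0.0)
    phi[never, :] = 0.0
    phi[:, never] = 0.0
    return GeneSpace(
        proximity=phi,
        gene_ids=rca_matrix.gene_ids,
        never_advantaged=never,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(space: GeneSpace) -> GeneSpace:
    """Maximum spanning forest of the proximity network (Kruskal).

    Edges are considered in (weight descending, index pair ascending) order,
    so ties resolve deterministically.  Zero-weight edges are not part of
    the graph; the result spans each connected component separately.
    """
    phi = space.proximity
    n = phi.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = phi[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))  # primary: weight desc; then (i, j) asc
    uf = _UnionFind(n)
    edges: List[Tuple[int, int, float]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        if uf.union(a, b):
            edges.append((a, b, float(w[idx])))
    space.mst_edges = edges
    return space


def gene_degrees(space: GeneSpace, graph: str = "threshold:0") -> np.ndarray:
    """Degree of each gene in the chosen view of the gene space.

    ``graph`` is one of ``"full"`` (count every positive proximity, same as
    ``"threshold:0"``), ``"threshold:<x>"`` (count edges with proximity
    strictly above x) or ``"mst"`` (degree within the maximum spanning
    tree).  The default counts all positive-proximity neighbours: MST
    degrees are nearly constant and carry little of the core/periphery
    signal.
    """
    phi = space.proximity
    n = phi.shape[0]
    if graph == "mst":
        if space.mst_edges is None:
            raise ValidationError("mst_edges not populated; run maximum_spanning_tree")
        deg = np.zeros(n, dtype=int)
        for a, b, _ in space.mst_edges:
            deg[a] += 1
            deg[b] += 1
        return deg
    if graph == "full":
        thr = 0.0
    elif graph.startswith("threshold:"):
        thr = float(graph.split(":", 1)[1])
    else:
        raise ValidationError(f"unknown degree graph {graph!r}")
    adj = phi > thr
    np.fill_diagonal(adj, False)
    return adj.sum(axis=1).astype(int)


def mean_expressed_degree(
    matrix: ExpressionMatrix,
    space: GeneSpace,
    graph: str = "threshold:0",
) -> np.ndarray:
    """Average gene-space degree of the genes each cell expresses.

    Cells whose expressed genes sit in the connected core score high; this
    is the cell-level summary of where a cell's expression pattern lives in
    the gene space.
    """
    if matrix.n_genes != space.proximity.shape[0]:
        raise ValidationError(
            f"matrix has {matrix.n_genes} genes but gene space has "
            f"{space.proximity.shape[0]}"
        )
    deg = gene_degrees(space, graph=graph).astype(np.float64)
    support = matrix.values.copy()
    support.data = np.ones_like(support.data)
    counts = np.asarray(support.sum(axis=1)).ravel()
    if (counts == 0).any():
        raise ValidationError("some cells express no genes; run filter_empty first")
    return np.asarray(support @ deg).ravel() / counts


def build_gene_space(matrix: ExpressionMatrix, threshold: float = 1.0) -> GeneSpace:
    """Convenience: RCA → proximity → MST → full-graph degrees."""
    r = rca(matrix)
    r.threshold = threshold
    space = proximity(r)
    space = maximum_spanning_tree(space)
    space.degree = gene_degrees(space)
    return space
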