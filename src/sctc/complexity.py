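"""Multi-order transcriptional complexity: method of reflections and the
analytic eigenvector solution.

The model
---------
Let ``M`` be the cells x genes expression matrix, viewed as a weighted
bipartite network.  Zeroth-order complexity is degree:

    k_{c,0} = sum_g M_cg        (cell diversity)
    k_{g,0} = sum_c M_cg        (gene ubiquity)

Higher orders are defined by the *method of reflections*, the alternating
recursion in which a cell's complexity at order N is the expression-weighted
mean of the complexities of its genes at order N-1, and symmetrically for
genes:

    k_{c,N} = (1/k_{c,0}) sum_g M_cg k_{g,N-1}
    k_{g,N} = (1/k_{g,0}) sum_c M_cg k_{c,N-1}

Substituting one equation into the other shows that even-order cell
complexity evolves under a row-stochastic cell-cell matrix

    Mtilde[c,c'] = sum_g M_cg M_c'g / (k_{c,0} k_{g,0})

whose leading eigenvector is constant (eigenvalue 1, the fixed point the
recursion collapses to).  The informative direction is the eigenvector K of
the *second-largest* eigenvalue; its sign is fixed by requiring a positive
Spearman correlation with cell diversity, and its min-max normalization is
the Cell Complexity Index (CCI).  The Gene Complexity Index (GCI) is one
reflection step applied to CCI, normalized.  Pseudotime is 1 - CCI: high
complexity marks high developmental potential, i.e. early cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .matrix import DegeneracyError, ExpressionMatrix, ValidationError

__all__ = [
    "ComplexityTable",
    "ComplexityIndices",
    "CellCellMatrix",
    "diversity",
    "ubiquity",
    "reflections",
    "build_cell_cell_matrix",
    "analytic_cci",
    "gci_from_cci",
    "cci_from_external_gci",
    "pseudotime",
    "convergence_threshold",
    "select_order",
    "order_pseudotime",
    "minmax",
]

#: cells above this count switch the eigensolver from dense to sparse iterative
DENSE_EIGEN_CUTOFF = 2000


def minmax(v: np.ndarray) -> np.ndarray:
    """Min-max scale a vector to [0, 1]; constant vectors raise."""
    v = np.asarray(v, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegeneracyError("cannot min-max normalize a constant vector")
    return (v - lo) / (hi - lo)


def diversity(matrix: ExpressionMatrix) -> np.ndarray:
    """Cell diversity k_{c,0}: total expression (bipartite degree) per cell."""
    k = matrix.row_sums()
    if (k <= 0).any():
        raise ValidationError("matrix has all-zero cells; run filter_empty first")
    return k


def ubiquity(matrix: ExpressionMatrix) -> np.ndarray:
    """Gene ubiquity k_{g,0}: total expression (bipartite degree) per gene."""
    k = matrix.col_sums()
    if (k <= 0).any():
        raise ValidationError("matrix has all-zero genes; run filter_empty first")
    return k


@dataclass
class ComplexityTable:
    """Per-order complexity vectors for cells and genes.

    ``cell_complexity[:, N]`` holds k_{c,N}, ``gene_complexity[:, N]`` holds
    k_{g,N}.  When ``normalized`` is set for a column, that column is the
    min-max scaled complexity of order N (computed by the numerically stable
    normalized recursion); the unscaled recursion values are in ``raw_cell``
    and ``raw_gene``, which collapse toward the constant fixed point at high
    order and are kept for convergence diagnostics.
    """

    cell_complexity: np.ndarray
    gene_complexity: np.ndarray
    normalized: np.ndarray
    N_max: int
    cell_ids: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None
    raw_cell: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    raw_gene: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class ComplexityIndices:
    """Analytic complexity indices and their eigen metadata."""

    cci: Optional[np.ndarray] = None
    gci: Optional[np.ndarray] = None
    second_eigenvalue: Optional[float] = None
    sign_scc: Optional[float] = None
    K_raw: Optional[np.ndarray] = None
    Q_raw: Optional[np.ndarray] = None
    cell_ids: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None


@dataclass
class CellCellMatrix:
    """Row-stochastic cell-cell matrix Mtilde (random walk through shared genes)."""

    values: np.ndarray
    source_dims: tuple


def reflections(
    matrix: ExpressionMatrix,
    N_max: int,
    normalize_each_order: bool = True,
) -> ComplexityTable:
    """Run the method of reflections up to order ``N_max``.

    Column N of the cell table is the k_{c,0}-weighted average of gene
    column N-1 and vice versa.  Reported columns are min-max scaled when
    ``normalize_each_order``; raw columns are kept on the result
    (``raw_cell`` / ``raw_gene``) for convergence diagnostics.
    """
    if N_max < 0:
        raise ValidationError(f"N_max must be >= 0, got {N_max}")
    kc0 = diversity(matrix)
    kg0 = ubiquity(matrix)
    M = matrix.values

    raw_c = np.empty((matrix.n_cells, N_max + 1))
    raw_g = np.empty((matrix.n_genes, N_max + 1))
    raw_c[:, 0] = kc0
    raw_g[:, 0] = kg0
    for N in range(1, N_max + 1):
        raw_c[:, N] = (M @ raw_g[:, N - 1]) / kc0
        raw_g[:, N] = (M.T @ raw_c[:, N - 1]) / kg0

    if normalize_each_order:
        # The reflection step is an affine-equivariant positive averaging:
        # feeding it a min-max rescaled vector rescales its output by the
        # same positive affine map, so iterating on *normalized* columns
        # yields exactly minmax(raw column) at every order — but without the
        # floating-point collapse of the raw recursion, whose deviations from
        # the constant fixed point shrink geometrically and drown in
        # round-off long before high orders.  The normalized recursion is
        # therefore run independently rather than derived from raw columns.
        cell = np.empty_like(raw_c)
        gene = np.empty_like(raw_g)
        cell[:, 0] = _minmax_or_const(kc0)
        gene[:, 0] = _minmax_or_const(kg0)
        for N in range(1, N_max + 1):
            cell[:, N] = _minmax_or_const((M @ gene[:, N - 1]) / kc0)
            gene[:, N] = _minmax_or_const((M.T @ cell[:, N - 1]) / kg0)
        normalized = np.ones(N_max + 1, dtype=bool)
    else:
        cell, gene = raw_c.copy(), raw_g.copy()
        normalized = np.zeros(N_max + 1, dtype=bool)

    return ComplexityTable(
        cell_complexity=cell,
        gene_complexity=gene,
        normalized=normalized,
        N_max=N_max,
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        raw_cell=raw_c,
        raw_gene=raw_g,
    )


def _minmax_or_const(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-300:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def build_cell_cell_matrix(matrix: ExpressionMatrix) -> CellCellMatrix:
    """Build Mtilde[c,c'] = sum_g M_cg M_c'g / (k_{c,0} k_{g,0}).

    Every row sums to 1: summing over c' gives sum_g M_cg * (k_{g,0}/k_{g,0})
    / k_{c,0} = 1, so Mtilde is the transition matrix of a random walk from
    cell to cell through a shared gene.
    """
    kc0 = diversity(matrix)
    kg0 = ubiquity(matrix)
    M = matrix.values
    # D_c^{-1} M D_g^{-1} M^T  (kept dense; cells x cells)
    W = M.multiply(1.0 / kg0[None, :]).tocsr()
    Mt = (M @ W.T).toarray()
    Mt /= kc0[:, None]
    return CellCellMatrix(values=Mt, source_dims=(matrix.n_cells, matrix.n_genes))


def _check_connected(matrix: ExpressionMatrix) -> None:
    """The second eigenvector encodes component membership, not development,
    on a disconnected bipartite network — refuse loudly."""
    n_c, n_g = matrix.n_cells, matrix.n_genes
    B = matrix.values
    graph = sp.bmat([[None, B], [B.T, None]], format="csr")
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise DegeneracyError(
            f"bipartite expression network has {n_comp} connected components; "
            "analyze each component separately"
        )


def _second_eigenpair(matrix: ExpressionMatrix, seed: int = 0):
    """Second-largest (algebraic) eigenpair of Mtilde.

    Mtilde = D_c^{-1} M D_g^{-1} M^T is similar, via D_c^{1/2}, to the
    symmetric PSD matrix S = D_c^{-1/2} M D_g^{-1} M^T D_c^{-1/2}; its
    spectrum is therefore real and lies in [0, 1].  We diagonalize S (dense
    below DENSE_EIGEN_CUTOFF cells, Lanczos with a seeded start vector
    above) and map eigenvectors back with D_c^{-1/2}.
    """
    kc0 = diversity(matrix)
    kg0 = ubiquity(matrix)
    M = matrix.values
    inv_sqrt_kc = 1.0 / np.sqrt(kc0)
    n = matrix.n_cells

    if n <= DENSE_EIGEN_CUTOFF:
        W = M.multiply(1.0 / kg0[None, :]).tocsr()
        S = (M @ W.T).toarray()
        S *= inv_sqrt_kc[:, None]
        S *= inv_sqrt_kc[None, :]
        S = 0.5 * (S + S.T)
        evals, evecs = np.linalg.eigh(S)
        lam1, lam2, lam3 = evals[-1], evals[-2], (evals[-3] if n >= 3 else -np.inf)
        v2 = evecs[:, -2]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        A = M.multiply(1.0 / kg0[None, :]).tocsr()
        Msqrt = sp.diags(inv_sqrt_kc) @ M
        Asqrt = sp.diags(inv_sqrt_kc) @ A

        def matvec(x):
            return Msqrt @ (Asqrt.T @ x)

        op = spla.LinearOperator((n, n), matvec=matvec, dtype=np.float64)
        evals, evecs = spla.eigsh(op, k=3, which="LA", v0=v0)
        order = np.argsort(evals)
        lam1, lam2, lam3 = evals[order[-1]], evals[order[-2]], evals[order[-3]]
        v2 = evecs[:, order[-2]]

    if lam1 - lam2 < 1e-10:
        raise DegeneracyError(
            "second eigenvalue is not separated from the trivial eigenvalue 1; "
            "the matrix carries no heterogeneity to resolve"
        )
    if lam2 - lam3 < 1e-10:
        raise DegeneracyError(
            "second eigenvalue has multiplicity > 1 (gap < 1e-10); the complexity "
            "direction is not unique — perturb the matrix or analyze components"
        )
    K = v2 * inv_sqrt_kc  # back-transform: eigenvector of Mtilde itself
    return float(lam2), K


def analytic_cci(matrix: ExpressionMatrix, seed: int = 0) -> ComplexityIndices:
    """Analytic Cell Complexity Index.

    CCI is the min-max normalized eigenvector K of Mtilde for its
    second-largest eigenvalue, with the sign of K chosen so that its
    Spearman correlation with cell diversity is positive (diversity is a
    positively-oriented, if imperfect, proxy for developmental potential).
    """
    _check_connected(matrix)
    lam2, K = _second_eigenpair(matrix, seed=seed)

    kc0 = diversity(matrix)
    rho = spearmanr(K, kc0).statistic
    if np.isnan(rho) or rho == 0:
        raise DegeneracyError(
            "orientation undefined: Spearman correlation between the second "
            "eigenvector and diversity is zero; supply stage labels or inspect "
            "the eigenvector manually"
        )
    if rho < 0:
        K = -K
        rho = -rho

    cci = minmax(K)
    return ComplexityIndices(
        cci=cci,
        second_eigenvalue=lam2,
        sign_scc=float(rho),
        K_raw=K,
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
    )


def gci_from_cci(matrix: ExpressionMatrix, indices: ComplexityIndices) -> ComplexityIndices:
    """Gene Complexity Index: one reflection step applied to CCI.

    Q_g = (1/k_{g,0}) sum_c M_cg CCI_c, then min-max normalized.  Computing
    GCI from CCI (rather than from the gene-side eigenproblem) avoids a
    second independent sign choice.
    """
    if indices.cci is None:
        raise ValidationError("indices.cci must be populated before computing gci")
    kg0 = ubiquity(matrix)
    Q = (matrix.values.T @ indices.cci) / kg0
    indices.Q_raw = Q
    indices.gci = minmax(Q)
    indices.gene_ids = matrix.gene_ids
    return indices


def cci_from_external_gci(
    matrix: ExpressionMatrix,
    external_gci: "pd.Series | dict | np.ndarray",
    external_gene_ids=None,
) -> ComplexityIndices:
    """Transfer gene complexity from another dataset onto this one's cells.

    One reflection step with foreign gene complexities: each cell scores the
    expression-weighted average of the external GCI over the genes shared
    between the two datasets, then min-max normalized to a CCI-like index.
    Genes absent from the external table are ignored (the weighted average
    renormalizes over shared genes only).
    """
    import pandas as pd

    if isinstance(external_gci, pd.Series):
        table = external_gci
    elif isinstance(external_gci, dict):
        table = pd.Series(external_gci)
    else:
        if external_gene_ids is None:
            raise ValidationError("external_gene_ids required when external_gci is an array")
        table = pd.Series(np.asarray(external_gci, dtype=float), index=external_gene_ids)

    own = pd.Index(matrix.gene_ids.astype(str))
    shared = own.intersection(pd.Index(table.index.astype(str)))
    if len(shared) == 0:
        raise ValidationError(
            "no genes shared between the matrix and the external GCI table; "
            "check gene identifier conventions"
        )
    mask = own.isin(shared)
    sub = matrix.values[:, mask]
    g = table.reindex(own[mask]).to_numpy(dtype=float)
    weights = np.asarray(sub.sum(axis=1)).ravel()
    if (weights <= 0).any():
        raise ValidationError(
            f"{int((weights <= 0).sum())} cells express none of the shared genes"
        )
    scores = (sub @ g) / weights
    cci = minmax(scores)
    return ComplexityIndices(cci=cci, K_raw=scores, cell_ids=matrix.cell_ids)


def pseudotime(indices: ComplexityIndices) -> np.ndarray:
    """Developmental pseudotime 1 - CCI: max-complexity cells are earliest."""
    if indices.cci is None:
        raise ValidationError("indices.cci must be populated")
    return 1.0 - indices.cci


def order_pseudotime(table: ComplexityTable, matrix: ExpressionMatrix, N: int) -> np.ndarray:
    """Pseudotime from a single even-order complexity column.

    A finite-order column carries the same directional ambiguity as the
    eigenvector it converges to (its deviation from the constant fixed
    point may align with +K or -K depending on how diversity projects onto
    the spectrum), so the column is oriented by the same rule as the
    analytic index — positive Spearman correlation with diversity — before
    being normalized and reversed into a pseudotime.
    """
    if not 0 <= N <= table.N_max:
        raise ValidationError(f"order {N} outside table range 0..{table.N_max}")
    col = table.cell_complexity[:, N].astype(float)
    if np.ptp(col) == 0:
        raise DegeneracyError(f"cell complexity column {N} is constant")
    rho = spearmanr(col, diversity(matrix)).statistic
    if np.isnan(rho) or rho == 0:
        raise DegeneracyError(f"orientation of order-{N} column is undefined")
    if rho < 0:
        col = -col
    return 1.0 - minmax(col)


def convergence_threshold(table: ComplexityTable, tol: float) -> Optional[int]:
    """Smallest even order at which normalized cell complexity has collapsed.

    Returns the first even N where the range (max - min) of the *raw*
    cell column, rescaled by the column mean, falls below ``tol`` —
    i.e. the order beyond which the reflections recursion has converged to
    the constant fixed point.  Returns None when not reached within N_max.
    """
    if tol <= 0:
        return None
    raw = table.raw_cell if table.raw_cell is not None else table.cell_complexity
    for N in range(0, table.N_max + 1, 2):
        col = raw[:, N]
        scale = np.abs(col).max()
        rng = col.max() - col.min()
        if scale == 0 or rng / scale < tol:
            return N
    return None


def select_order(table: ComplexityTable, indices: ComplexityIndices) -> int:
    """Even order whose cell column best matches the analytic CCI (by SCC).

    Ties break toward the smaller order.  The analytic index is the
    converged limit of the even-order recursion, so this picks the smallest
    order that already carries the full-ranking information.
    """
    if indices.cci is None:
        raise ValidationError("indices.cci must be populated")
    best_N, best_rho = 0, -np.inf
    for N in range(0, table.N_max + 1, 2):
        col = table.cell_complexity[:, N]
        if np.ptp(col) == 0:
            continue
        rho = spearmanr(col, indices.cci).statistic
        if np.isnan(rho):
            continue
        if rho > best_rho + 1e-15:
            best_rho, best_N = rho, N
    return best_N
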