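"""Independent brute-force oracles: explicit loops and exhaustive searches,
deliberately written without reusing any vectorized package code."""

from __future__ import annotations

import itertools

import numpy as np


def diversity_loop(M: np.ndarray) -> np.ndarray:
    out = np.zeros(M.shape[0])
    for c in range(M.shape[0]):
        for g in range(M.shape[1]):
            out[c] += M[c, g]
    return out


def ubiquity_loop(M: np.ndarray) -> np.ndarray:
    out = np.zeros(M.shape[1])
    for g in range(M.shape[1]):
        for c in range(M.shape[0]):
            out[g] += M[c, g]
    return out


def reflections_loop(M: np.ndarray, n_max: int):
    """k_{c,N} and k_{g,N} by direct evaluation of the recursion."""
    n_cells, n_genes = M.shape
    kc = np.zeros((n_cells, n_max + 1))
    kg = np.zeros((n_genes, n_max + 1))
    kc[:, 0] = diversity_loop(M)
    kg[:, 0] = ubiquity_loop(M)
    for N in range(1, n_max + 1):
        for c in range(n_cells):
            acc = 0.0
            for g in range(n_genes):
                acc += M[c, g] * kg[g, N - 1]
            kc[c, N] = acc / kc[c, 0]
        for g in range(n_genes):
            acc = 0.0
            for c in range(n_cells):
                acc += M[c, g] * kc[c, N - 1]
            kg[g, N] = acc / kg[g, 0]
    return kc, kg


def cell_cell_loop(M: np.ndarray) -> np.ndarray:
    kc0 = diversity_loop(M)
    kg0 = ubiquity_loop(M)
    n = M.shape[0]
    out = np.zeros((n, n))
    for c in range(n):
        for c2 in range(n):
            for g in range(M.shape[1]):
                out[c, c2] += M[c, g] * M[c2, g] / (kc0[c] * kg0[g])
    return out


def rca_loop(M: np.ndarray) -> np.ndarray:
    grand = M.sum()
    out = np.zeros_like(M, dtype=float)
    for c in range(M.shape[0]):
        cell_tot = M[c].sum()
        for g in range(M.shape[1]):
            gene_tot = M[:, g].sum()
            if gene_tot == 0 or cell_tot == 0:
                out[c, g] = 0.0
            else:
                out[c, g] = (M[c, g] / cell_tot) / (gene_tot / grand)
    return out


def proximity_loop(advantage: np.ndarray) -> np.ndarray:
    """phi from explicit conditional-probability counts on a boolean matrix."""
    n_genes = advantage.shape[1]
    phi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(n_genes):
            ni = int(advantage[:, i].sum())
            nj = int(advantage[:, j].sum())
            both = int((advantage[:, i] & advantage[:, j]).sum())
            if ni == 0 or nj == 0:
                phi[i, j] = 0.0
            else:
                phi[i, j] = min(both / nj, both / ni)
    return phi


def mst_exhaustive(weights: np.ndarray) -> float:
    """Maximum spanning tree weight by enumerating all spanning trees.

    Only feasible for small n (n <= 7): iterates over all (n-1)-edge
    subsets and keeps the best one that is connected and acyclic.
    Assumes the positive-weight graph is connected.
    """
    n = weights.shape[0]
    edges = [(i, j, weights[i, j]) for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0]
    best = -np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b, _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[rb] = ra
        if ok:
            best = max(best, sum(w for _, _, w in subset))
    return best


def spearman_formula(x, y) -> float:
    """Spearman rho via Pearson on average ranks, computed by hand."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
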