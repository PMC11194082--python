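# sctc — single-cell transcriptional complexity

`sctc` infers developmental pseudotime and developmental potential from an
scRNA-seq count matrix alone, using ideas from economic complexity theory.
It is aimed at researchers ordering cells along differentiation when no
trusted reference or training data exists — in particular in the regime
where the popular gene-count heuristic breaks down because the *earliest*
cells express *fewer* genes than their immediate descendants.

## The model

The expression matrix `M` (cells × genes) is read as a weighted bipartite
network. Zeroth-order complexity is degree:

    k_{c,0} = Σ_g M_cg   (cell diversity)
    k_{g,0} = Σ_c M_cg   (gene ubiquity)

Higher orders come from the **method of reflections** — a cell is complex
if it expresses complex genes, and vice versa:

    k_{c,N} = (1/k_{c,0}) Σ_g M_cg k_{g,N-1}
    k_{g,N} = (1/k_{g,0}) Σ_c M_cg k_{c,N-1}

Substituting one recursion into the other shows even-order cell complexity
evolves under the row-stochastic cell–cell matrix

    M̃_cc' = Σ_g M_cg M_c'g / (k_{c,0} k_{g,0}),

a random walk from cell to cell through a shared gene. Its leading
eigenvector is constant (the fixed point the recursion collapses into); the
informative direction is the eigenvector **K** of the second-largest
eigenvalue. Oriented to correlate positively with diversity and min–max
normalized, K is the **Cell Complexity Index (CCI)**; one more reflection
step gives the **Gene Complexity Index (GCI)**, and pseudotime is `1 − CCI`
(high complexity = high potential = early).

The package also builds the **gene space**: revealed comparative advantage
`RCA_cg = (M_cg/Σ_g M_cg) / (Σ_c M_cg/Σ_cg M_cg)` marks which genes a cell
expresses *prominently*; the proximity of two genes is the smaller of the
two conditional probabilities of being co-advantaged, and the maximum
spanning tree of the proximity network summarizes its backbone. Cells with
high CCI express genes from the densely connected core of this network.

Evaluation utilities score any pseudotime against stage labels (Spearman
correlation), measure stage separation along complexity features
(silhouette over orders), rank genes by complexity, and run dropout
robustness protocols. A synthetic-trajectory generator with known ground
truth (nested gene tiers, configurable early-diversity dip, lognormal
weights, dropout) makes every claim testable offline.

## Worked example

```
python examples/pseudotime_basics.py
```

prints (seed 1):

```
trajectory: 200 cells x 400 genes, 4 stages
second eigenvalue of the cell-cell matrix: 0.5444
SCC(complexity pseudotime, stage) = 0.9481
SCC(diversity pseudotime,  stage) = 0.4383
```

The generated trajectory has an early diversity dip: stage-0 cells express
fewer genes than stage-1 cells but concentrate on a core gene tier. The
complexity pseudotime recovers the true stage order almost perfectly
(Spearman 0.95) while the expressed-gene-count baseline, which assumes
diversity falls monotonically with time, lands at 0.44. The second
eigenvalue (0.54 < 1) is the spectral gap that makes the analytic index
well-defined.

Other examples cover order-by-order convergence of the recursion
(`reflections_orders.py`), the gene space and mean expressed degree
(`gene_space_core.py`), cross-dataset GCI→CCI transfer (`transfer_gci.py`)
and dropout robustness (`dropout_robustness.py`).

A thin CLI wraps the same functions for shell use, e.g.

```
sctc simulate --out sim.csv --labels labels.csv --seed 2
sctc cci sim.csv --out indices.csv
sctc evaluate sim.csv --labels labels.csv --out report.json
```

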