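# Methods

## Model and assumptions

`sctc` treats a cells × genes expression matrix `M` as the weighted
adjacency matrix of a bipartite network and ranks both node classes by
*complexity*. The working hypothesis, imported from economic complexity
theory, is that a cell's developmental potential is encoded in *which*
genes it expresses — specifically, whether they sit in the core of the
gene co-expression structure — rather than in *how many*. The method
assumes:

* non-negative expression values; any monotone preprocessing (library-size
  normalization, log transform) is acceptable because every reported
  quantity is rank-based downstream;
* a single connected bipartite component. On a disconnected network the
  second eigenvector of the cell–cell matrix encodes component membership
  rather than a developmental gradient, so `analytic_cci` refuses and asks
  for per-component analysis;
* a simple (non-degenerate) second eigenvalue. Exactly uniform matrices,
  or matrices whose second eigenspace has multiplicity > 1 (gap below
  1e-10), raise a degeneracy error rather than returning an arbitrary
  vector;
* diversity is a *positively oriented* (though possibly weak) proxy for
  potential. The sign of the second eigenvector is fixed by requiring a
  positive Spearman correlation with diversity; if the true biology were
  anti-correlated with diversity overall, the orientation rule — and hence
  the sign of pseudotime — would be wrong. The correlation used for the
  decision is recorded on the result (`sign_scc`) so borderline
  orientations are visible.

## The recursion and its numerics

The method of reflections alternates weighted averages between the two
node classes. Substitution shows even-order cell complexity evolves under
the row-stochastic matrix `M̃ = D_c⁻¹ M D_g⁻¹ Mᵀ`, whose spectrum is real
(it is similar via `D_c^{1/2}` to a symmetric positive-semidefinite
matrix; the implementation diagonalizes that symmetric form and asserts
the similarity transform back). "Second-largest eigenvalue" means by
algebraic value, the convention of the economic-complexity literature; the
spectrum being real and in [0, 1], this coincides with modulus except for
the trivial eigenvalue 1.

Two numerical points matter:

* **Normalized vs raw recursion.** Raw complexities converge to a
  constant; deviations shrink like `λ₂^{N/2}` and fall below float64
  resolution long before the *ranking* has converged when `λ₃/λ₂` is close
  to 1 (observed 0.85–0.92 on realistic fixtures, where exact rank
  convergence needs N ≈ 100–200). The reflection step is an affine
  positive-scale-equivariant map, so min–max rescaling each order is
  mathematically transparent: the normalized recursion's columns equal
  `minmax(raw column)` exactly in exact arithmetic, while remaining
  numerically stable at any order. Reported (normalized) columns therefore
  come from the renormalized recursion; raw columns are kept alongside for
  convergence diagnostics.
* **Convergence threshold N_th.** Defined on the raw recursion as the
  first even order whose relative range `(max − min)/max|·|` falls below
  `tol` (a min–max normalized column has range 1 by construction, so the
  threshold must be read off the raw values). `tol ≤ 0` returns the
  "not reached" sentinel.

Finite-order columns used as pseudotime carry the same ±K directional
ambiguity as the eigenvector (the deviation from the fixed point may align
with +K or −K depending on the sign of diversity's spectral projection),
so `order_pseudotime` applies the same diversity-orientation rule before
normalizing. Order selection (`select_order`) picks the even order whose
column best rank-correlates with the analytic index, ties toward smaller
orders.

The eigensolver is dense (`numpy.linalg.eigh`) below 2 000 cells and a
seeded Lanczos iteration (`scipy.sparse.linalg.eigsh`, top-3 eigenpairs,
fixed start vector) above, so results are deterministic for a given seed.

## Gene space

RCA uses threshold 1 ("a larger share of the cell's output than of the
global output"); proximity is `min` of the two conditional co-advantage
probabilities, computed from exact contingency counts; genes never
advantaged anywhere have undefined conditionals and are assigned proximity
0 with a warning. The maximum spanning tree is Kruskal with edges ordered
(weight descending, index pair ascending), so ties resolve
deterministically and the output is invariant to relabeling up to the
declared tie rule.

For the mean-expressed-degree analysis the degree graph defaults to "all
positive-proximity edges" but is selectable (`full`, `threshold:<x>`,
`mst`). On dense synthetic data the positive-proximity graph saturates
(nearly every gene pair shares at least one co-advantaged cell, making all
degrees ≈ G−1), so the synthetic protocols and the corresponding example
read degree in the strong-edge graph (`threshold:0.5`), where the
core-tier clique is visible. MST degrees are near-constant by construction
and mostly useful as a null.

## Evaluation choices

* Accuracy is Spearman correlation between a pseudotime and integer-coded
  stage labels; the stage order is always user-declared, never inferred
  from label text. Ties get average ranks; tied cells keep input order.
* The silhouette over orders uses the per-cell unweighted mean of the
  order-N gene column over expressed genes as a 1-D feature. By default it
  is computed on feature *values* (the protocol the order-trend analysis
  uses). Distance-based silhouette is **not** invariant under monotone
  transforms of the feature; `use_ranks=True` computes it on ranks, which
  is. Both variants are exposed because the invariance matters when
  comparing features whose scales are arbitrary.
* The diversity baseline is the min–max normalized expressed-gene count —
  the core assumption of gene-count potency scores, implemented plainly.
  It is *not* a reimplementation of any published tool (no gene-count
  signature smoothing, no Markov diffusion), and comparisons against it
  are labeled "diversity baseline" accordingly.
* Marker detection for the concordance protocol wraps scanpy's Wilcoxon
  rank-sum ranking (top 10 per stage by default) and is approximate; an
  externally supplied marker table is used identically.
* Dropout simulation zeroes each nonzero entry independently with the
  given probability, then drops empty rows/columns (stage labels follow
  the surviving cells). The robustness protocol re-runs both pseudotimes
  per (rate, repeat) and reports mean ± sd accuracy per rate; all repeat
  seeds derive from one seed via `SeedSequence`.

## Synthetic data: what it emulates and what it does not

The generator produces a staged trajectory with tiered genes. A cell of
stage `s` expresses its own tier with probability 0.9, later tiers with
probability `nestedness` (default 0.5, producing the triangular/nested
occupancy the complexity machinery exploits), and earlier tiers at 0.05 —
so early tiers stay nearly private to early cells (low ubiquity, high
complexity). Expressed weights are lognormal (median 5, σ = `noise_sd`,
default 0.5) because scRNA-seq magnitudes are heavy-tailed.

Two diversity regimes are built in:

* `monotone` — expressed-gene counts decrease strictly with stage; a
  diversity ranking alone already orders the cells (the "easy" regime).
  Used to check the comparison is not rigged and for
  recursion-vs-analytic agreement fixtures (40 cells × ~60 genes,
  N_max = 200, where rank agreement is exact).
* `dip_early` — stage-0 cells express the core tier at 0.95 but reach
  forward only with geometrically decaying probability
  (`dip_strength · dip_decay^{t−1}`, defaults 0.25 and 0.5), so they
  express *fewer* genes than stage-1 cells while remaining adjacent to
  stage 1 on the similarity gradient. The decay is what keeps the
  developmental chain intact; a uniform weak reach instead isolates
  stage 0 into its own cluster and the second eigenvector degenerates to
  a stage-0-vs-rest indicator. Defaults were calibrated once against the
  loop-oracle recursion during development and then frozen. The
  order-progression protocols use a shallower dip (`dip_strength = 0.35`):
  with a deep dip, low orders (N ≤ 4) have not yet disentangled the early
  stages — the depth of the dip controls how many reflection rounds are
  needed, mirroring the way different real datasets need different orders.

The generator does **not** model library-size variation, batch effects,
doublets, UMI counting noise, or zero-inflation beyond independent
dropout. Passing the synthetic protocols therefore demonstrates that the
implementation recovers the structure the model targets under its own
assumptions — not that those assumptions hold in any particular real
dataset.

Problem sizes throughout the test and acceptance protocols (200-cell
trajectories, 40-cell convergence fixtures, 10 seeds / 10 repeats) were
chosen as the smallest at which the rank statistics are stable; all
experiments complete in seconds.

## Known limitations

* A scalar ordering only: no branching, no trajectory graph.
* The orientation rule inherits diversity's sign; datasets where potential
  anti-correlates with diversity *overall* would be flipped end-to-end.
* The dense cell–cell matrix is the memory bottleneck (cells²); above the
  dense-solver cutoff the matrix is never materialized, but silhouette and
  robustness protocols still scale with cells × genes.
* RCA is scale-free per cell but not invariant under log transforms;
  whether to build the gene space from raw or log-normalized values is a
  user decision (both are accepted; results differ).
* With heavy dropout plus small matrices, `filter_empty` can remove cells,
  so compared vectors must always be taken from the surviving matrix (the
  robustness utilities do this automatically).
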