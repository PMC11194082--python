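"""Synthetic developmental trajectories with known ground truth.

The generator emulates the two regimes observed in real developmental
scRNA-seq atlases:

* ``monotone`` — transcriptional diversity (number of expressed genes)
  decreases monotonically along development, so a diversity-rank baseline
  already orders cells correctly (the "easy" regime, e.g. human
  spermatogenesis).
* ``dip_early`` — the earliest cells express *fewer* genes than the next
  stage while concentrating their expression on a private core tier of
  genes.  Diversity then mis-orders the early stages, but the bipartite
  network structure (which genes, not how many) still identifies them —
  the regime where complexity-based ordering earns its keep.

Structure: genes come in tiers aligned with stages.  A cell of stage ``s``
expresses its own tier with high probability, neighbouring tiers with
moderate probability (so consecutive stages share support and the cells
form a chain in similarity space), later tiers with probability
``nestedness`` (early cells reach forward into the broadly-expressed
periphery — the nested, triangular shape of the matrix) and earlier tiers
only rarely (core tiers stay nearly private to early cells, which keeps
their ubiquity low and their complexity high).  Expressed weights are
lognormal — scRNA-seq magnitudes are heavy-tailed — and independent
Bernoulli dropout can be applied on top.

Defaults (4 stages x 50 cells, 4 tiers x 100 genes) keep every experiment
in the package fast while leaving enough cells per stage for rank
statistics to be stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .matrix import ExpressionMatrix, ValidationError

__all__ = ["TrajectoryConfig", "generate_trajectory", "generate_twin_datasets", "toy_bipartite_fixture"]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Knobs of the trajectory generator.

    ``nestedness`` is the probability that a cell expresses a gene from a
    tier later than its own stage (beyond the immediately adjacent tier);
    ``noise_sd`` is the sigma of the lognormal weight distribution;
    ``dip_strength`` and ``dip_decay`` only matter under
    ``diversity_profile="dip_early"``: stage-0 cells express tier t >= 1
    with probability ``dip_strength * dip_decay**(t-1)``, so they reach
    forward with geometric decay — the smaller these are, the deeper the
    early diversity dip.
    """

    n_stages: int = 4
    cells_per_stage: int = 50
    n_gene_tiers: int = 4
    genes_per_tier: int = 100
    nestedness: float = 0.5
    diversity_profile: str = "dip_early"
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0
    p_own: float = 0.9
    p_adjacent: float = 0.3
    p_back: float = 0.05
    dip_strength: float = 0.25
    dip_decay: float = 0.5

    def __post_init__(self):
        if min(self.n_stages, self.cells_per_stage, self.n_gene_tiers, self.genes_per_tier) <= 0:
            raise ValidationError("all counts must be positive")
        for name in ("nestedness", "dropout_rate", "p_own", "p_adjacent", "p_back",
                     "dip_strength", "dip_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.diversity_profile not in ("monotone", "dip_early"):
            raise ValidationError(
                f"diversity_profile must be 'monotone' or 'dip_early', got {self.diversity_profile!r}"
            )


def _expression_probability(cfg: TrajectoryConfig, stage: int, tier: int) -> float:
    """P(cell of *stage* expresses a given gene of *tier*)."""
    if tier == stage:
        p = cfg.p_own
    elif tier == stage + 1:
        p = max(cfg.p_adjacent, cfg.nestedness)
    elif tier > stage + 1:
        p = cfg.nestedness
    else:
        p = cfg.p_back
    if cfg.diversity_profile == "dip_early" and stage == 0:
        # Earliest cells concentrate on the near-private core tier and reach
        # forward with geometrically decaying probability.  The decay keeps
        # them adjacent to stage 1 on the similarity gradient (so the chain
        # stays intact) while their expressed-gene count dips below stage 1.
        if tier == 0:
            p = min(1.0, cfg.p_own + 0.05)
        else:
            p = cfg.dip_strength * cfg.dip_decay ** (tier - 1)
    return p


def generate_trajectory(
    config: TrajectoryConfig,
) -> Tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Draw one trajectory.

    Returns ``(matrix, stage_labels, gene_tiers)``; ``stage_labels`` is also
    attached to the matrix.  Fully determined by ``config`` (including its
    seed).  Cells left empty by dropout are dropped (with their labels);
    the caller still owns the decision to run :func:`sctc.preprocess.filter_empty`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S, C, T, G = cfg.n_stages, cfg.cells_per_stage, cfg.n_gene_tiers, cfg.genes_per_tier
    n_cells, n_genes = S * C, T * G

    stage_of_cell = np.repeat(np.arange(S), C)
    tier_of_gene = np.repeat(np.arange(T), G)

    P = np.empty((n_cells, n_genes))
    for s in range(S):
        t_of_s = min(s, T - 1)
        row = np.array([_expression_probability(cfg, t_of_s, t) for t in range(T)])
        P[stage_of_cell == s] = row[tier_of_gene][None, :]

    expressed = rng.random((n_cells, n_genes)) < P
    weights = rng.lognormal(mean=np.log(5.0), sigma=cfg.noise_sd, size=(n_cells, n_genes))
    X = np.where(expressed, weights, 0.0)

    if cfg.dropout_rate > 0:
        drop = rng.random((n_cells, n_genes)) < cfg.dropout_rate
        X[drop] = 0.0

    cell_ids = np.array([f"s{stage_of_cell[i]}_c{i}" for i in range(n_cells)], dtype=object)
    gene_ids = np.array([f"t{tier_of_gene[j]}_g{j}" for j in range(n_genes)], dtype=object)
    stages = stage_of_cell.astype(object)

    keep = X.sum(axis=1) > 0
    if not keep.all():
        X, cell_ids, stages = X[keep], cell_ids[keep], stages[keep]
    present = np.unique(stages.astype(int))
    if len(present) < S:
        raise ValidationError("a stage ended up with no cells; lower dropout_rate")

    matrix = ExpressionMatrix(sp.csr_matrix(X), cell_ids, gene_ids, stages)
    return matrix, matrix.stage_labels, tier_of_gene


def generate_twin_datasets(
    config: TrajectoryConfig,
    overlap: float = 1.0,
    shift: float = 0.0,
) -> Tuple[ExpressionMatrix, ExpressionMatrix, np.ndarray]:
    """Two trajectories sharing a fraction ``overlap`` of their genes.

    Twin B keeps the shared genes (same identifiers, same tiers) and
    replaces the rest with its own genes drawn from the same tier layout;
    ``shift`` tilts B's stage proportions (weights ∝ exp(shift·s)) to make
    the populations heterogeneous.  Returns (A, B, shared_gene_ids).
    Used for the gene-complexity transfer protocol: GCI fitted on A,
    applied to B's cells through the shared genes.
    """
    if not 0.0 < overlap <= 1.0:
        raise ValidationError(f"overlap must be in (0, 1], got {overlap}")
    cfg_a = config
    a, _, tiers = generate_trajectory(cfg_a)

    rng = np.random.default_rng(config.seed + 100_003)
    n_genes = config.n_gene_tiers * config.genes_per_tier
    n_shared = int(round(overlap * n_genes))
    shared_idx = np.sort(rng.choice(n_genes, size=n_shared, replace=False))

    # twin B: same tier layout, different cells, optionally tilted stages
    S, C = config.n_stages, config.cells_per_stage
    w = np.exp(shift * np.arange(S, dtype=float))
    counts = np.maximum(1, np.round(w / w.sum() * S * C).astype(int))
    cfg_b = replace(config, seed=config.seed + 200_003)
    b_full, _, _ = generate_trajectory(replace(cfg_b, cells_per_stage=max(counts.max(), 1)))
    # subsample B's cells to the tilted per-stage counts
    stages_b = b_full.stage_labels.astype(int)
    keep_rows: List[int] = []
    for s in range(S):
        rows = np.flatnonzero(stages_b == s)
        take = min(counts[s], len(rows))
        keep_rows.extend(rows[:take].tolist())
    b = b_full.subset(cell_mask=np.array(sorted(keep_rows)))

    # rename B's non-shared genes so only the overlap is identifier-shared
    gene_ids_b = b.gene_ids.copy()
    shared_mask = np.zeros(n_genes, dtype=bool)
    shared_mask[shared_idx] = True
    for j in np.flatnonzero(~shared_mask):
        gene_ids_b[j] = f"B_{gene_ids_b[j]}"
    b = ExpressionMatrix(b.values, np.array([f"B_{c}" for c in b.cell_ids], dtype=object),
                         gene_ids_b, b.stage_labels)
    return a, b, a.gene_ids[shared_mask]


def toy_bipartite_fixture() -> ExpressionMatrix:
    """A fixed 4-cell x 4-gene weighted toy network.

    Small integer weights with heterogeneous diversity and ubiquity; used
    in unit tests and the documentation walk-through.  Row sums (diversity)
    are (8, 3, 7, 4); column sums (ubiquity) are (3, 3, 9, 7).
    """
    M = np.array(
        [
            [1, 2, 3, 2],
            [0, 1, 2, 0],
            [2, 0, 1, 4],
            [0, 0, 3, 1],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        sp.csr_matrix(M),
        cell_ids=np.array(["c0", "c1", "c2", "c3"], dtype=object),
        gene_ids=np.array(["g0", "g1", "g2", "g3"], dtype=object),
    )
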