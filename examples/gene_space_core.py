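"""Build the RCA-based gene space and relate it to cell complexity.

Computes revealed comparative advantage, gene-gene proximities, the
maximum spanning tree, and each cell's mean expressed-gene degree in the
strong-proximity graph — high-complexity cells express genes from the
densely connected core.
"""

import numpy as np
from scipy.stats import pearsonr

from sctc import (
    TrajectoryConfig,
    analytic_cci,
    build_gene_space,
    diversity,
    filter_empty,
    generate_trajectory,
    mean_expressed_degree,
)

matrix, stages, _ = generate_trajectory(TrajectoryConfig(seed=1))
matrix = filter_empty(matrix)

space = build_gene_space(matrix)
n_edges = int((space.proximity > 0.5).sum() - np.trace(space.proximity > 0.5)) // 2
print(f"gene space: {matrix.n_genes} genes, "
      f"{len(space.mst_edges)} spanning-tree edges, "
      f"{n_edges} strong edges (proximity > 0.5)")

mean_deg = mean_expressed_degree(matrix, space, graph="threshold:0.5")
cci = analytic_cci(matrix).cci
r_cci = pearsonr(mean_deg, cci).statistic
r_div = pearsonr(mean_deg, diversity(matrix)).statistic
print(f"PCC(mean expressed degree, CCI)       = {r_cci:+.3f}")
print(f"PCC(mean expressed degree, diversity) = {r_div:+.3f}")
print(
    "\nCells scoring high on the complexity index express genes sitting in\n"
    "the tightly interconnected core of the gene space; raw expression\n"
    "diversity tracks that position much more weakly."
)
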