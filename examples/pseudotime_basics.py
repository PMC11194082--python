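"""Infer developmental pseudotime from a synthetic trajectory.

Generates a 4-stage trajectory in the 'dip_early' regime — the earliest
cells express *fewer* genes than stage-1 cells, so a gene-count baseline
mis-orders them — then computes the analytic Cell Complexity Index and
compares both pseudotimes against the known stages.
"""

from sctc import (
    TrajectoryConfig,
    analytic_cci,
    diversity_baseline,
    filter_empty,
    generate_trajectory,
    pseudotime,
    scc_vs_labels,
)

matrix, stages, _ = generate_trajectory(TrajectoryConfig(seed=1))
matrix = filter_empty(matrix)
print(f"trajectory: {matrix.n_cells} cells x {matrix.n_genes} genes, "
      f"{len(set(stages))} stages")

indices = analytic_cci(matrix)
pt_sctc = pseudotime(indices)
pt_diversity = 1.0 - diversity_baseline(matrix)

print(f"second eigenvalue of the cell-cell matrix: {indices.second_eigenvalue:.4f}")
print(f"SCC(complexity pseudotime, stage) = {scc_vs_labels(pt_sctc, stages):.4f}")
print(f"SCC(diversity pseudotime,  stage) = {scc_vs_labels(pt_diversity, stages):.4f}")
print(
    "\nThe complexity index recovers the stage order (SCC near 1) while the\n"
    "expressed-gene-count baseline is thrown off by the early diversity dip."
)
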