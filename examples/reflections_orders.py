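"""Watch the method of reflections converge order by order.

Runs the alternating cell/gene recursion on a shallow-dip trajectory,
scores each even-order cell column as a pseudotime, and shows where the
recursion collapses (N_th) and which order already matches the analytic
eigenvector index (N*).
"""

from sctc import (
    TrajectoryConfig,
    analytic_cci,
    convergence_threshold,
    filter_empty,
    generate_trajectory,
    order_pseudotime,
    reflections,
    scc_vs_labels,
    select_order,
)

matrix, stages, _ = generate_trajectory(TrajectoryConfig(dip_strength=0.35, seed=1))
matrix = filter_empty(matrix)

table = reflections(matrix, N_max=100)
indices = analytic_cci(matrix)

print("order N   SCC(order-N pseudotime, stage)")
for N in (0, 2, 4, 6, 8):
    scc = scc_vs_labels(order_pseudotime(table, matrix, N), stages)
    print(f"  {N:3d}      {scc:+.4f}")

n_star = select_order(table, indices)
n_th = convergence_threshold(table, tol=1e-3)
print(f"\nselected order N* (best match to analytic CCI): {n_star}")
print(f"convergence threshold N_th (raw recursion collapses, tol 1e-3): {n_th}")
print(
    "\nOrder 0 is raw diversity and mis-ranks the early stages; a few\n"
    "reflection rounds integrate network structure and fix the ordering.\n"
    "The raw recursion values flatten to a constant at N_th — the ranking\n"
    "refined past that point (up to N*) is exactly what the analytic\n"
    "eigenvector index captures in closed form."
)
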