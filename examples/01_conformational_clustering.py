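"""Joint conformational clustering of a multi-variant synthetic collection.

Builds four variant ensembles whose loop conformations are drawn from three
distinct templates with variant-specific mixture weights, then runs the full
pipeline: all-pairs fitted RMSD (fit on the framework backbone, RMSD over
the loop), greedy neighbour-count clustering at a 0.2 nm cutoff, the 2 %
overall-occurrence filter, and the per-variant occupancy report.
"""

import numpy as np

from cdrloop import (
    TemplateMixtureSpec,
    build_rmsd_matrix,
    filter_clusters,
    greedy_neighbor_cluster,
    make_loop_system,
    make_template_set,
    occupancy_report,
    sample_mixture_ensembles,
)

system = make_loop_system(seed=7)
templates = make_template_set(system, n_templates=3, separation=0.5)
weights = {
    "wt-like": np.array([0.7, 0.2, 0.1]),
    "variant-1": np.array([0.1, 0.7, 0.2]),
    "variant-2": np.array([0.2, 0.1, 0.7]),
    "variant-3": np.array([0.34, 0.33, 0.33]),
}
spec = TemplateMixtureSpec(
    topology=system.topology,
    templates=templates,
    loop_indices=system.loop_indices,
    mixture_weights=weights,
    noise_sigma=0.03,  # nm, per axis, loop atoms only
    n_frames=200,
    seed=7,
)
ensembles, truth = sample_mixture_ensembles(spec)

matrix = build_rmsd_matrix(ensembles, system.fit_expression, system.loop_expression)
clusters = greedy_neighbor_cluster(matrix, cutoff=0.2)
kept = filter_clusters(clusters, min_overall_fraction=0.02)

print(f"pooled frames: {matrix.n_frames}")
print(f"clusters found: {len(clusters)}, kept at >=2% occurrence: {len(kept)}")
print()
print(occupancy_report(kept).round(3))
print()
print("Each row is one variant; each column the fraction of its frames in")
print("that conformational cluster (rows sum to 1).  The recovered")
print("occupancies track the generator's mixture weights, so a shift in the")
print("dominant cluster between variants reflects a real conformational")
print("preference, not sampling noise.")
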