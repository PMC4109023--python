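"""Cluster a 52-surface × 8-parameter panel into thrombus types I–III.

Generates a panel with a planted 3-type structure, normalizes each parameter
to 0–10, clusters surfaces (Euclidean, complete linkage), attaches multiscale
bootstrap AU support, and cuts the tree at k = 3.
"""

import thromboquant as tq

truth = tq.planted_matrix_truth(seed=7)
_means, replicates = tq.gen_parameter_matrix(truth)

pm = tq.normalize_matrix(tq.aggregate_replicates(replicates))
tree = tq.hcluster(pm.normalized)
tree = tq.multiscale_bootstrap(pm.normalized, tree, n_boot=1000, seed=7)
assignment = tq.cut_types(tree, pm.normalized, k=3)

for rec in assignment.mapping:
    print(
        f"type {'I' * 0 + ['I', 'II', 'III'][rec['type'] - 1]:>3}: "
        f"{rec['size']:2d} surfaces, mean normalized activation {rec['mean_value']:.2f}"
    )

from sklearn.metrics import adjusted_rand_score

ari = adjusted_rand_score(truth.true_type, assignment.types.to_numpy())
print(f"agreement with the planted types (ARI): {ari:.2f}")

strong = (tree.support["au"] >= 0.90).sum()
print(f"clusters with AU ≥ 0.90: {strong} of {len(tree.support)}")
print("newick head:", tq.newick_export(tree)[:80], "...")

# ARI = 1 means the k = 3 cut reproduces the planted types exactly; AU ≥ 0.90
# marks clusters that survive the multiscale bootstrap (strong support).
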