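"""Cluster multi-tissue MAFs from the published tissue table.

Square-root-transformed MAFs are compared by Euclidean distance and merged
by average linkage (UPGMA); tissues of the same carrier and tissues sharing
a germ layer end up close together.
"""
import numpy as np

from ddmosaic import (
    build_maf_matrix,
    dendrogram_to_newick,
    hierarchical_cluster,
    load_fixture,
    sqrt_euclidean_distances,
)

tissue = load_fixture("tissue_maf")
rows = [
    {"row_id": f"{r.family_id}_{r.tissue}", "feature": "maf",
     "value": r.maf / 100.0}
    for r in tissue.itertuples()
    if np.isfinite(r.maf)
]
matrix = build_maf_matrix(rows, na_policy="drop_feature")
dists = sqrt_euclidean_distances(matrix)
tree = hierarchical_cluster(dists, linkage="average")

print(f"{len(tree.labels)} samples clustered; first merge at height "
      f"{tree.heights[0]:.4f}, last at {tree.heights[-1]:.4f}")
print(dendrogram_to_newick(tree))
# In the Newick tree, near-zero-MAF samples (e.g. the A065 father's somatic
# tissues) form one tight subtree while the high-MAF carrier tissues (A052
# mother, A112 father) merge at much larger heights.
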