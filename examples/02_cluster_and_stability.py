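"""Cluster simulated cells and pick a resolution by stability.

Clustering is z-score -> PCA -> shared-nearest-neighbour graph -> Louvain.
`explore_param` sweeps resolutions reporting intrinsic quality metrics;
`clust_stability` reruns each resolution with fresh seeds and scores
run-to-run agreement by the adjusted Rand index (ARI).
"""

from dataclasses import replace

from cytotype import ClusterParams, SimSpec, dominant_marker_reference, simulate
from cytotype.clustering import clust_stability, explore_param

events = simulate(
    SimSpec.single_sample(dominant_marker_reference(4), [0.25] * 4, 2000, seed=1)
)

base = ClusterParams(k_neighbors=40, n_components=4, seed=0)
grid = [replace(base, resolution=r) for r in (0.1, 0.4, 0.8)]
table = explore_param(events, grid)
print("resolution sweep (higher silhouette / CH, lower DB = tighter clusters):")
print(
    table[["resolution", "n_clusters", "silhouette", "calinski_harabasz",
           "davies_bouldin"]].round(3).to_string(index=False)
)

stability = clust_stability(events, base, resolutions=(0.1, 0.4, 0.8), n_rep=5)
print("\nstability over 5 reseeded runs (ARI 1 = identical partitions):")
print(stability.table.round(3).to_string(index=False))
print(f"\nmost stable resolution: {stability.best_resolution()}")
print("Four planted populations: the stable resolutions recover 4 clusters.")
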