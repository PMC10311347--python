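"""Chemical-series-aware train/test splitting.

Generates pseudo-fingerprints with 12 planted clusters, recovers them with
Butina leader clustering at Tanimoto >= 0.8, and assigns whole clusters to
the test partition so no chemical series straddles the evaluation boundary.
"""

from dtitransfer import butina_cluster, cluster_split
from dtitransfer.synthetic import generate_pseudo_fingerprints

fingerprints, planted = generate_pseudo_fingerprints(
    n_clusters=12, cluster_size=10, seed=7
)
clusters = butina_cluster(fingerprints, cutoff=0.8)
print(f"compounds: {len(fingerprints)}, recovered clusters: {clusters.n_clusters} "
      f"(planted: {len(set(planted.values()))})")

split = cluster_split(list(fingerprints), clusters, test_fraction=1 / 6, seed=1)
print(f"train {len(split.train_ids)} / test {len(split.test_ids)} "
      f"(target test fraction 1/6 of {len(fingerprints)})")

# verify no cluster is split across partitions
straddling = sum(
    1 for c in clusters.centroids
    if set(clusters.members(c)) & split.train_ids
    and set(clusters.members(c)) & split.test_ids
)
print(f"clusters straddling the boundary: {straddling}")
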