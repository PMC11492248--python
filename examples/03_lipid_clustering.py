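"""Recover planted GM3 lipid clusters with DBSCAN.

Plants three 10-molecule GM3 blobs in the upper leaflet and clusters
the species' centres of geometry with DBSCAN (eps 28 A, minimum 5
molecules), the parameters that minimise the unclustered GM3 group.
"""

from memscope import (SurfaceParams, cluster_series, make_membrane_frame,
                      plant_species_clusters)

frame, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=450,
                               box=(500, 500, 500), seed=3)
frame, truth = plant_species_clusters(frame, "DPG3", k=3, size=10,
                                      spread=12.0, seed=3)

leaflets = {m: ("upper" if m <= 450 else "lower") for m in range(1, 901)}
table, labelings = cluster_series([frame], "DPG3", leaflet="upper",
                                  leaflet_map=leaflets)

print(table.to_string(index=False))
print("planted cluster sizes:", truth.cluster_sizes())
recovered = labelings[0]
print(f"recovered: {recovered.n_clusters} clusters, "
      f"{recovered.n_noise} noise molecules")
# n_clusters=3 with mean_size=10 and the remaining GM3 as noise means
# the planted memberships were recovered exactly; on real trajectories
# the same series (clusters, mean size, noise) is tracked per frame.
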