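"""Select a chemically diverse odor panel from a descriptor matrix.

Builds a blob-structured synthetic descriptor space (standing in for the
real odorants x physicochemical-descriptor matrix), clusters it with seeded
k-means, and picks one representative per cluster, preferring odorants
already known to activate a receptor.
"""

from orfunc import select_panel, simulate_descriptor_space

dm = simulate_descriptor_space(n=500, d=20, n_blobs=8, seed=3,
                               active_fraction=0.15)
panel = select_panel(dm, k=8, seed=3)

print(f"{dm.X.shape[0]} odorants x {dm.X.shape[1]} descriptors "
      f"-> {panel.k} clusters, one selection each:\n")
print(panel.table.to_string(index=False))
n_active = (panel.table["rule_used"] == "active_nearest").sum()
print(f"\n{n_active}/{panel.k} selections are known actives near their"
      " centroid; the rest fall back to the nearest member")
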