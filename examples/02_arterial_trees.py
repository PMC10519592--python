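"""Grow the two-level arterial trees and inspect their diameters.

Partitions a sphere cortex into coarse regions, grows a coarse binary
tree per territory and a fine tree per coarse terminal, assigns Murray
diameters, and prints the resulting diameter scales.
"""

import numpy as np

from cerebroflow import (
    TreeGrowthParams,
    assign_diameters_murray,
    assign_regions_to_territories,
    generate_seed_arteries,
    generate_synthetic_cortex,
    grow_coarse_trees,
    grow_fine_trees,
    partition_surface,
)
from cerebroflow.anastomoses import terminal_edge_diameters

mesh = generate_synthetic_cortex(5120, semi_axes=(60.0, 60.0, 60.0), seed=1)
seeds = generate_seed_arteries(mesh, seed=1)
params = TreeGrowthParams(seed=1)

coarse = partition_surface(mesh, 48, seed=1)
territory = assign_regions_to_territories(mesh, coarse, seeds)
net = grow_coarse_trees(mesh, coarse, seeds, params, territory)
print(f"coarse trees: {net.n_nodes} nodes, {net.n_edges} edges "
      f"({coarse.region_count} terminals, one per region)")

fine = {
    r: partition_surface(mesh, 8, seed=100 + r,
                         triangle_subset=coarse.region_triangles(r),
                         level="fine", parent_region=r)
    for r in range(coarse.region_count)
}
net = grow_fine_trees(mesh, net, fine, params)
net = assign_diameters_murray(net, params)
print(f"with fine trees: {net.n_nodes} nodes, {net.n_edges} edges")

d_coarse = np.array(list(terminal_edge_diameters(net, "coarse_terminal").values()))
d_fine = np.array(list(terminal_edge_diameters(net, "fine_terminal").values()))
print(f"coarse terminal branch diameters: median {np.median(d_coarse):.0f} um "
      f"(range {d_coarse.min():.0f}-{d_coarse.max():.0f})")
print(f"fine terminal branch diameters:   median {np.median(d_fine):.0f} um "
      f"(range {d_fine.min():.0f}-{d_fine.max():.0f})")
print("fine branches sit one diameter scale below the coarse branches, "
      "as Murray's law dictates for the extra bifurcation levels")
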