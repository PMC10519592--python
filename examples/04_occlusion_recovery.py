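"""Occlude the RMCA trunk and quantify collateral flow recovery.

Solves the normal and occluded states (99% diameter reduction of the
right-MCA trunk), then reports the flow recovery ratio
q_occlusion / q_normal per fine subregion and in total, with the
area-weighted histogram used to characterize the ischemic territory.
"""

import numpy as np

from cerebroflow import (
    OcclusionSpec,
    apply_occlusion,
    areal_fraction_histogram,
    assemble_and_solve,
    boundary_conditions_for,
    build_network,
    flow_recovery,
    smoke_config,
)

build = build_network(smoke_config(seed=0))
bcs = boundary_conditions_for(build)
sol_normal = assemble_and_solve(build.net, bcs)

occ = OcclusionSpec(target_edge=build.trunk_edge, diameter_scale=0.01)
sol_occluded = assemble_and_solve(apply_occlusion(build.net, occ), bcs)

rep = flow_recovery(build.net, bcs, sol_normal, sol_occluded,
                    build.subregion_areas, "RMCA")
qn = rep.territory_flows_normal["RMCA"]
qo = rep.territory_flows_occluded["RMCA"]
print(f"RMCA territory flow: {qn:.2f} -> {qo:.3f} mL/min under occlusion")
print(f"total flow recovery ratio (pial collaterals only): "
      f"{100 * rep.total_recovery:.2f}%")

bins = (0.0, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 1.0, np.inf)
frac = areal_fraction_histogram(rep, bins)
print("area fraction of the RMCA territory by recovery ratio:")
for lo, hi, f in zip(bins[:-1], bins[1:], frac):
    if f > 0:
        print(f"  {100 * lo:5.0f}%-{100 * hi:5.0f}%: {100 * f:5.1f}% of area")
print("without intermediate anastomoses, almost the whole territory sits "
      "in the lowest recovery bins - the dense pial loops alone cannot "
      "re-supply a territory whose trunk is occluded")
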