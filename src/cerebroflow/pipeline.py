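"""End-to-end pipeline: generate -> solve -> occlude -> report -> select.

``build_network`` assembles the full multiscale network from a
configuration; ``run_pipeline`` additionally solves the normal and
occluded states, quantifies recovery and (optionally) runs greedy
anastomosis selection, writing every artifact plus a provenance
manifest to the output directory.  Identical configurations reproduce
identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .anastomoses import (
    PialNetworkParams,
    attach_penetrating_arterioles,
    build_pial_network,
    connect_tree_terminals_to_pial,
    find_candidate_pairs,
)
from .config import RunConfig
from .flow import (
    BoundaryConditions,
    assemble_and_solve,
    calibrate_bed_pressure,
    check_mass_balance,
    compute_terminal_resistances,
    total_inflow_ml_min,
)
from .experiments import (
    OcclusionSpec,
    apply_occlusion,
    flow_recovery,
    greedy_anastomosis_selection,
)
from .geometry import (
    SurfaceMesh,
    generate_seed_arteries,
    generate_synthetic_cortex,
    load_mesh,
)
from .network import ROLE_INLET, VascularNetwork
from .treegen import (
    RegionPartition,
    TreeGrowthParams,
    assign_diameters_murray,
    assign_regions_to_territories,
    find_rmca_trunk_edge,
    grow_coarse_trees,
    grow_fine_trees,
    murray_root_diameters,
    partition_surface,
    subdivide_and_project_edges,
)

log = logging.getLogger("cerebroflow")


@dataclass
class NetworkBuild:
    """Everything produced by the construction stages."""

    config: RunConfig
    mesh: SurfaceMesh
    coarse_partition: RegionPartition
    region_territory: np.ndarray
    fine_partitions: dict
    triangle_region: np.ndarray
    triangle_subregion: np.ndarray
    subregion_areas: np.ndarray  # indexed by global subregion id
    net: VascularNetwork
    candidates: list
    trunk_edge: int


def build_network(config: RunConfig) -> NetworkBuild:
    """Construct the complete multiscale arterial network.

    Stages: cortex surface, territory seeds, coarse/fine partitions,
    coarse and fine tree growth, Murray diameters, tier-2 candidate
    detection, edge subdivision + surface projection, pial dual-graph
    layer with penetrating arterioles, and terminal wiring.
    """
    t0 = time.time()
    g = config.geometry
    if g.mesh_path:
        mesh = load_mesh(g.mesh_path)
    else:
        mesh = generate_synthetic_cortex(
            g.target_triangle_count,
            semi_axes=g.semi_axes_mm,
            wrinkle_amplitude=g.wrinkle_amplitude_mm,
            wrinkle_frequency=g.wrinkle_frequency,
            seed=config.seed,
        )
    seeds = generate_seed_arteries(
        mesh, root_diameters=config.tree.root_diameters_um, seed=config.seed
    )
    log.info("mesh: %d triangles, %.0f mm^2 (%.1fs)", mesh.n_triangles,
             mesh.total_area, time.time() - t0)

    params = TreeGrowthParams(
        total_flow_ml_min=config.flow.total_flow_ml_min,
        murray_exponent=config.tree.murray_exponent,
        terminal_diameter_floor_um=config.tree.terminal_diameter_floor_um,
        cco_candidate_connections=config.tree.cco_candidate_connections,
        seed=config.seed,
    )
    coarse = partition_surface(mesh, config.tree.n1, seed=config.seed)
    territory = assign_regions_to_territories(mesh, coarse, seeds)
    if config.tree.root_diameter_mode == "murray":
        shares = {
            t: float(
                coarse.region_areas[territory == t].sum() / mesh.total_area
            )
            for t in set(territory)
        }
        seeds = generate_seed_arteries(
            mesh,
            root_diameters=murray_root_diameters(
                shares, config.tree.root_diameters_um
            ),
            seed=config.seed,
        )
    net = grow_coarse_trees(mesh, coarse, seeds, params, territory)
    log.info("coarse trees: %d nodes, %d edges (%.1fs)", net.n_nodes, net.n_edges,
             time.time() - t0)

    fine_partitions = {}
    for r in range(coarse.region_count):
        tris = coarse.region_triangles(r)
        n2 = min(config.tree.n2, len(tris))
        fine_partitions[r] = partition_surface(
            mesh,
            n2,
            seed=config.seed * 1_000_003 + r,
            triangle_subset=tris,
            level="fine",
            parent_region=r,
        )
    net = grow_fine_trees(mesh, net, fine_partitions, params)
    log.info("fine trees: %d nodes, %d edges (%.1fs)", net.n_nodes, net.n_edges,
             time.time() - t0)

    # global fine-subregion labels per triangle, aligned with treegen's
    # deterministic numbering (sorted region order)
    triangle_region = coarse.full_assignment(mesh.n_triangles)
    triangle_subregion = np.full(mesh.n_triangles, -1, dtype=np.int64)
    sub_areas = []
    offset = 0
    for r in sorted(fine_partitions):
        part = fine_partitions[r]
        triangle_subregion[part.triangle_ids] = offset + part.labels
        sub_areas.append(part.region_areas)
        offset += part.region_count
    subregion_areas = np.concatenate(sub_areas)

    fine_terms = net.nodes_with_role("fine_terminal")
    overrides = {
        int(n): float(
            params.total_flow_ml_min
            * subregion_areas[net.node_subregion[n]]
            / mesh.total_area
        )
        for n in fine_terms
    }
    net = assign_diameters_murray(net, params, overrides)

    candidates = []
    for other in ("RACA", "RPCA"):
        candidates.extend(
            find_candidate_pairs(
                net, mesh, triangle_region, territory, "RMCA", other
            )
        )
    candidates.sort(key=lambda c: (c.separation_mm, c.terminal_a, c.terminal_b))
    for i, c in enumerate(candidates):
        c.candidate_id = i
    if config.experiment.max_candidates is not None:
        candidates = candidates[: config.experiment.max_candidates]
    log.info("tier-2 candidates: %d", len(candidates))

    net = subdivide_and_project_edges(net, mesh)

    triangle_territory = np.array(
        [territory[r] if r >= 0 else "" for r in triangle_region], dtype=object
    )
    pial_params = PialNetworkParams(
        pial_diameter_um=config.pial.pial_diameter_um,
        penetrating_diameter_um=config.pial.penetrating_diameter_um,
        target_density_per_mm2=config.pial.target_density_per_mm2,
    )
    pial = build_pial_network(
        mesh,
        pial_params,
        triangle_territory=triangle_territory,
        triangle_region=triangle_region,
        triangle_subregion=triangle_subregion,
    )
    pial = attach_penetrating_arterioles(pial, mesh, pial_params)
    net = connect_tree_terminals_to_pial(net, pial)
    trunk = find_rmca_trunk_edge(net)
    log.info("combined network: %d nodes, %d edges (%.1fs)", net.n_nodes,
             net.n_edges, time.time() - t0)
    return NetworkBuild(
        config=config,
        mesh=mesh,
        coarse_partition=coarse,
        region_territory=territory,
        fine_partitions=fine_partitions,
        triangle_region=triangle_region,
        triangle_subregion=triangle_subregion,
        subregion_areas=subregion_areas,
        net=net,
        candidates=candidates,
        trunk_edge=trunk,
    )


def boundary_conditions_for(build: NetworkBuild, calibrate: bool = True) -> BoundaryConditions:
    """Terminal-resistance boundary conditions for a built network.

    Each penetrating terminal's nominal flow is the areal share of its
    source triangle; the bed pressure is calibrated so normal-condition
    total inflow matches the configured total cerebral flow (unless a
    fixed value is configured).
    """
    net = build.net
    fc = build.config.flow
    terms = net.nodes_with_role("penetrating_terminal")
    # penetrating terminal order mirrors triangle order within the pial
    # block, but map via subregion-areas-independent triangle areas:
    # terminal i was created from pial node i which is triangle i.
    areas = build.mesh.triangle_areas
    terminal_areas = {int(t): float(areas[i]) for i, t in enumerate(terms)}
    inlets = net.nodes_with_role(ROLE_INLET)
    bcs = compute_terminal_resistances(
        terminal_areas,
        build.mesh.total_area,
        inlet_nodes=[int(i) for i in inlets],
        inlet_pressure_mmhg=fc.inlet_pressure_mmhg,
        total_flow_ml_min=fc.total_flow_ml_min,
        cortical_drop_mmhg=fc.cortical_drop_mmhg,
        bed_pressure_mmhg=fc.bed_pressure_mmhg or 0.0,
        viscosity_pa_s=fc.viscosity_pa_s,
    )
    if fc.bed_pressure_mmhg is None and calibrate:
        try:
            bcs = calibrate_bed_pressure(
                net,
                bcs,
                target_total_flow_ml_min=fc.total_flow_ml_min,
                tolerance_ml_min=fc.calibration_tolerance_ml_min,
                solver=fc.solver,
            )
        except ValueError as exc:
            # scaled-down fixtures cannot always reach the physiological
            # total inflow; operate at the closest achievable point
            # (p_0 = 0) — recovery metrics are flow ratios and remain
            # well-defined there
            log.warning("bed-pressure calibration fell back to p0 = 0: %s", exc)
            bcs = bcs.with_bed_pressure(0.0)
    return bcs


@dataclass
class PipelineResult:
    build: NetworkBuild
    bcs: BoundaryConditions
    sol_normal: object
    sol_occluded: object
    report: object
    selection: object = None
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute all stages and (optionally) write artifacts + manifest."""
    build = build_network(config)
    bcs = boundary_conditions_for(build)
    solver = config.flow.solver
    sol_normal = assemble_and_solve(build.net, bcs, solver=solver)
    occ = OcclusionSpec(
        target_edge=build.trunk_edge,
        diameter_scale=config.experiment.occlusion_diameter_scale,
    )
    net_occ = apply_occlusion(build.net, occ)
    sol_occ = assemble_and_solve(net_occ, bcs, solver=solver)
    report = flow_recovery(
        build.net, bcs, sol_normal, sol_occ, build.subregion_areas, "RMCA"
    )
    selection = None
    if config.experiment.run_selection and build.candidates:
        selection = greedy_anastomosis_selection(
            build.net, build.candidates, occ, bcs
        )

    result = PipelineResult(build, bcs, sol_normal, sol_occ, report, selection)
    if write:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    from . import serialize
    from .geometry import save_mesh

    config = result.build.config
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    build = result.build
    paths = {}

    def _reg(name, path):
        paths[name] = os.path.relpath(path, outdir)

    mesh_path = os.path.join(outdir, "cortex.ply")
    save_mesh(build.mesh, mesh_path)
    _reg("mesh", mesh_path)

    serialize.save_network_csv(build.net, os.path.join(outdir, "network"))
    _reg("network_nodes", os.path.join(outdir, "network.nodes.csv"))
    _reg("network_edges", os.path.join(outdir, "network.edges.csv"))
    serialize.save_network_vtp(
        build.net,
        os.path.join(outdir, "network.vtp"),
        point_data={"pressure_mmHg": result.sol_normal.pressures_mmhg},
        cell_data={"flow_ml_min": result.sol_normal.flows_ml_min},
    )
    _reg("network_vtp", os.path.join(outdir, "network.vtp"))

    serialize.candidates_to_frame(build.candidates).to_csv(
        os.path.join(outdir, "candidates.csv"), index=False
    )
    _reg("candidates", os.path.join(outdir, "candidates.csv"))

    serialize.save_solution_csv(
        build.net, result.sol_normal, os.path.join(outdir, "normal")
    )
    serialize.save_solution_csv(
        build.net, result.sol_occluded, os.path.join(outdir, "occluded")
    )
    for n in ("normal", "occluded"):
        _reg(f"{n}_pressures", os.path.join(outdir, f"{n}.pressures.csv"))
        _reg(f"{n}_flows", os.path.join(outdir, f"{n}.flows.csv"))

    serialize.recovery_report_to_frame(result.report).to_csv(
        os.path.join(outdir, "recovery_report.csv"), index=False
    )
    _reg("recovery_report", os.path.join(outdir, "recovery_report.csv"))

    import pandas as pd

    tf = pd.DataFrame(
        {
            "territory": list(result.report.territory_flows_normal),
            "flow_normal_ml_min": list(result.report.territory_flows_normal.values()),
            "flow_occluded_ml_min": list(
                result.report.territory_flows_occluded.values()
            ),
        }
    )
    tf.to_csv(os.path.join(outdir, "territory_flows.csv"), index=False)
    _reg("territory_flows", os.path.join(outdir, "territory_flows.csv"))

    if result.selection is not None:
        serialize.greedy_log_to_frame(result.selection).to_csv(
            os.path.join(outdir, "greedy_log.csv"), index=False
        )
        _reg("greedy_log", os.path.join(outdir, "greedy_log.csv"))

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "bed_pressure_mmhg": result.bcs.bed_pressure_mmhg,
        "n_nodes": build.net.n_nodes,
        "n_edges": build.net.n_edges,
        "n_candidates": len(build.candidates),
        "total_recovery": result.report.total_recovery,
        "artifacts": paths,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.artifacts = paths
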