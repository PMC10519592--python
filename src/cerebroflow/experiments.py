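"""Occlusion experiments and collateral-supply quantification.

The in silico protocol: solve the normal-condition flow, occlude the
RMCA trunk (99% diameter reduction by default), re-solve, and quantify
collateral supply through the flow recovery ratio

    recovery = q_occlusion / q_normal

evaluated per fine subregion (summing the penetrating-terminal outflows
assigned to it) and in total over the occluded territory.

Greedy anastomosis selection explores which intermediate anastomoses
matter most: each round evaluates every remaining candidate by solving
the occluded network with it temporarily added, permanently adopts the
best, and repeats — N(N+1)/2 occluded solves for N candidates instead
of 2^N.  Candidate evaluations reuse a single factorization of the
baseline system through exact low-rank (Woodbury) updates, which leaves
the solve count unchanged but makes each solve cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .flow import (
    BoundaryConditions,
    FlowSolution,
    FlowSystem,
    edge_conductance,
    terminal_outflows,
)
from .geometry import TERRITORIES
from .network import ROLE_PENETRATING_TERMINAL, VascularNetwork

DEFAULT_RECOVERY_BINS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 1.0, np.inf)


@dataclass
class OcclusionSpec:
    """Diameter-scaling occlusion of one edge (the RMCA trunk)."""

    target_edge: int
    diameter_scale: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.diameter_scale <= 1.0:
            raise ValueError("diameter_scale must be in (0, 1]")


def apply_occlusion(net: VascularNetwork, spec: OcclusionSpec) -> VascularNetwork:
    """Copy of the network with the target edge diameter scaled down
    (conductance scales with the fourth power)."""
    if not 0 <= spec.target_edge < net.n_edges:
        raise KeyError(f"edge {spec.target_edge} does not exist")
    out = net.copy()
    out.edge_diameter_um[spec.target_edge] *= spec.diameter_scale
    return out


# ----------------------------------------------------------------------
# recovery quantification


@dataclass
class RecoveryReport:
    """Per-subregion and territory-level flow recovery."""

    occluded_territory: str
    subregion_ids: np.ndarray
    subregion_areas_mm2: np.ndarray
    q_normal: np.ndarray
    q_occlusion: np.ndarray
    ratio: np.ndarray  # nan where undefined (q_normal ~ 0)
    total_recovery: float
    territory_flows_normal: dict
    territory_flows_occluded: dict

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.ratio)


def territory_flow_table(
    net: VascularNetwork, bcs: BoundaryConditions, sol: FlowSolution
) -> dict:
    """Total penetrating-terminal outflow (mL/min) per territory."""
    out = {t: 0.0 for t in TERRITORIES}
    q = terminal_outflows(net, bcs, sol)
    for node, flow in q.items():
        t = str(net.node_territory[node])
        if t in out:
            out[t] += flow
    return out


def flow_recovery(
    net: VascularNetwork,
    bcs: BoundaryConditions,
    sol_normal: FlowSolution,
    sol_occluded: FlowSolution,
    subregion_areas_mm2,
    occluded_territory: str = "RMCA",
    undefined_floor_ml_min: float = 1e-12,
) -> RecoveryReport:
    """Flow recovery ratios per fine subregion of the occluded territory.

    Both solutions must live on the same topology (occlusion changes a
    single diameter).  Subregions whose normal flow is below the floor
    are reported as undefined (nan) rather than clamped.
    """
    if len(sol_normal.pressures_mmhg) != len(sol_occluded.pressures_mmhg):
        raise ValueError("solutions computed on different topologies")
    terms = net.nodes_with_role(ROLE_PENETRATING_TERMINAL)
    in_terr = net.node_territory[terms] == occluded_territory
    terms = terms[in_terr]
    subs = net.node_subregion[terms]
    if np.any(subs < 0):
        raise ValueError("penetrating terminals lack subregion labels")

    qn_all = terminal_outflows(net, bcs, sol_normal)
    qo_all = terminal_outflows(net, bcs, sol_occluded)
    qn = np.array([qn_all[int(t)] for t in terms])
    qo = np.array([qo_all[int(t)] for t in terms])

    sub_ids = np.unique(subs)
    pos = {int(s): i for i, s in enumerate(sub_ids)}
    idx = np.array([pos[int(s)] for s in subs])
    q_normal = np.bincount(idx, weights=qn, minlength=len(sub_ids))
    q_occl = np.bincount(idx, weights=qo, minlength=len(sub_ids))
    ratio = np.where(q_normal > undefined_floor_ml_min, q_occl / np.where(
        q_normal > undefined_floor_ml_min, q_normal, 1.0), np.nan)

    areas = np.array([float(subregion_areas_mm2[int(s)]) for s in sub_ids])
    total = float(q_occl.sum() / q_normal.sum()) if q_normal.sum() > 0 else np.nan
    return RecoveryReport(
        occluded_territory=occluded_territory,
        subregion_ids=sub_ids,
        subregion_areas_mm2=areas,
        q_normal=q_normal,
        q_occlusion=q_occl,
        ratio=ratio,
        total_recovery=total,
        territory_flows_normal=territory_flow_table(net, bcs, sol_normal),
        territory_flows_occluded=territory_flow_table(net, bcs, sol_occluded),
    )


def areal_fraction_histogram(
    report: RecoveryReport, bin_edges=DEFAULT_RECOVERY_BINS
) -> np.ndarray:
    """Area-weighted histogram of recovery ratios over defined
    subregions; fractions sum to 1."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d = report.defined
    hist, _ = np.histogram(
        report.ratio[d], bins=edges, weights=report.subregion_areas_mm2[d]
    )
    total = report.subregion_areas_mm2[d].sum()
    return hist / total if total > 0 else hist


# ----------------------------------------------------------------------
# greedy anastomosis selection


@dataclass
class GreedySelectionResult:
    adopted_order: list
    recovery_curve: np.ndarray  # index n = best total recovery with n adopted
    solve_count: int
    evaluations: list = field(default_factory=list)  # (round, candidate, recovery)


class RecoveryEvaluator:
    """Total RMCA-territory recovery for an adopted anastomosis set.

    Holds a single factorization of the normal, anastomosis-free system;
    the trunk occlusion and every temporary anastomosis enter as exact
    rank-one conductance updates, so each candidate evaluation costs one
    pair of triangular solves instead of a refactorization.
    """

    def __init__(
        self,
        net: VascularNetwork,
        candidates: list,
        occlusion: OcclusionSpec,
        bcs: BoundaryConditions,
        occluded_territory: str | None = None,
    ):
        self.net = net
        self.bcs = bcs
        self.system = FlowSystem(net, bcs)
        if occluded_territory is None:
            tgt = int(net.edge_target[occlusion.target_edge])
            occluded_territory = str(net.node_territory[tgt])
        self.occluded_territory = occluded_territory
        term_terr = net.node_territory[self.system.term_nodes]
        self.territory_mask = term_terr == occluded_territory
        if not self.territory_mask.any():
            raise ValueError(
                f"no penetrating terminals in territory {occluded_territory!r}"
            )

        e = occlusion.target_edge
        k_trunk = float(
            edge_conductance(
                net.edge_diameter_um[e], net.edge_length_um[e], bcs.viscosity_pa_s
            )
        )
        self.trunk_update = (
            int(net.edge_source[e]),
            int(net.edge_target[e]),
            k_trunk * (occlusion.diameter_scale**4 - 1.0),
        )
        self.candidate_updates = {}
        for c in candidates:
            k_c = float(
                edge_conductance(
                    c.diameter_um,
                    max(c.separation_mm * 1.0e3, 1.0),
                    bcs.viscosity_pa_s,
                )
            )
            self.candidate_updates[c.candidate_id] = (
                int(c.terminal_a),
                int(c.terminal_b),
                k_c,
            )

    def _territory_flow(self, reduced: np.ndarray) -> float:
        p = self.system.full_pressures_pa(reduced)
        q = self.system.terminal_outflows_ml_min(p)
        return float(q[self.territory_mask].sum())

    def total_recovery(self, adopted, extra=None) -> float:
        """Recovery ratio with the adopted set (plus an optional
        temporary candidate): occluded / normal territory flow, both
        computed on the same anastomosed network."""
        cand = [self.candidate_updates[i] for i in adopted]
        if extra is not None:
            cand = cand + [self.candidate_updates[extra]]
        q_norm = self._territory_flow(self.system.solve_reduced(cand))
        q_occ = self._territory_flow(
            self.system.solve_reduced(cand + [self.trunk_update])
        )
        return q_occ / q_norm


def greedy_anastomosis_selection(
    net: VascularNetwork,
    candidates: list,
    occlusion: OcclusionSpec,
    bcs: BoundaryConditions | None = None,
    evaluate=None,
) -> GreedySelectionResult:
    """Iterative greedy adoption of intermediate anastomoses.

    Round r evaluates each of the N - r + 1 remaining candidates by
    computing the occluded-network total recovery with that candidate
    temporarily added to the adopted set, then permanently adopts the
    argmax (ties to the lowest candidate id).  ``solve_count`` counts
    every candidate evaluation — N(N+1)/2 in total.  ``evaluate`` may
    replace the physical evaluator (signature
    ``evaluate(adopted_tuple, candidate_or_None) -> float``), e.g. for
    counting experiments.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if evaluate is None:
        if bcs is None:
            raise ValueError("either boundary conditions or an evaluator is required")
        ev = RecoveryEvaluator(net, candidates, occlusion, bcs)
        evaluate = ev.total_recovery

    remaining = sorted(c.candidate_id for c in candidates)
    n_total = len(remaining)
    adopted: list = []
    curve = np.zeros(n_total + 1)
    curve[0] = evaluate((), None)  # pial-only baseline, not counted
    evaluations = []
    solve_count = 0
    for rnd in range(1, n_total + 1):
        best_id, best_rec = None, -np.inf
        for cand in remaining:  # ascending id: ties go to the lowest id
            rec = evaluate(tuple(adopted), cand)
            solve_count += 1
            evaluations.append((rnd, cand, float(rec)))
            if rec > best_rec:
                best_id, best_rec = cand, rec
        adopted.append(best_id)
        remaining.remove(best_id)
        curve[rnd] = best_rec
    return GreedySelectionResult(
        adopted_order=adopted,
        recovery_curve=curve,
        solve_count=solve_count,
        evaluations=evaluations,
    )
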