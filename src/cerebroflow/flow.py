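"""Steady 0D Poiseuille network flow.

Each vessel segment is a Poiseuille resistor with conductance

    k_ij = pi d_ij^4 / (128 mu L_ij),

and nodal mass balance sum_j k_ij (p_i - p_j) = 0 holds at every
interior node.  Boundary conditions: fixed pressure (100 mmHg) at the
four inlet nodes, and a terminal-resistance (Robin) outlet
p_i = p_0 + R_i q_i at every penetrating terminal, folded into the
system by elimination as a series conductance 1/R_i to a ghost node at
the vascular-bed pressure p_0 — which keeps the reduced system symmetric
positive definite.  Per-terminal resistances are set from a 65 mmHg
cortical pressure drop at the terminal's areal share of the 715 mL/min
total cerebral flow.

All assembly happens in SI; pressures are exchanged in mmHg and flows
in mL/min.  :class:`FlowSystem` additionally supports exact low-rank
(Woodbury) re-solves after conductance edits — scaling one edge or
adding a few anastomoses — which the occlusion/greedy experiments use to
avoid refactorizing the whole system for every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, spilu, splu, LinearOperator

from . import units
from .network import (
    ROLE_INLET,
    ROLE_PENETRATING_TERMINAL,
    VascularNetwork,
)

DEFAULT_VISCOSITY_PA_S = 3.5e-3
DEFAULT_INLET_PRESSURE_MMHG = 100.0
DEFAULT_TOTAL_FLOW_ML_MIN = 715.0
DEFAULT_CORTICAL_DROP_MMHG = 65.0
DIRECT_SOLVER_LIMIT = 50_000


def edge_conductance(diameter_um, length_um, viscosity_pa_s=DEFAULT_VISCOSITY_PA_S):
    """Poiseuille conductance k = pi d^4 / (128 mu L) in m^3 Pa^-1 s^-1.

    ``diameter_um`` and ``length_um`` are in micrometres; scalars or
    arrays.
    """
    d = np.asarray(diameter_um, dtype=float) * units.UM_TO_M
    L = np.asarray(length_um, dtype=float) * units.UM_TO_M
    if np.any(d <= 0) or np.any(L <= 0) or viscosity_pa_s <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    return np.pi * d**4 / (128.0 * viscosity_pa_s * L)


@dataclass
class BoundaryConditions:
    """Dirichlet inlet pressures plus Robin terminal resistances.

    ``terminal_resistances`` maps penetrating-terminal node id to R_i in
    mmHg.min/mL; ``bed_pressure_mmhg`` is the vascular-bed pressure p_0
    behind every terminal.
    """

    inlet_pressures_mmhg: dict
    terminal_resistances: dict
    bed_pressure_mmhg: float = 0.0
    nominal_total_flow_ml_min: float = DEFAULT_TOTAL_FLOW_ML_MIN
    cortical_drop_mmhg: float = DEFAULT_CORTICAL_DROP_MMHG
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S

    def __post_init__(self):
        if not self.inlet_pressures_mmhg:
            raise ValueError("at least one inlet pressure is required")
        if any(r <= 0 for r in self.terminal_resistances.values()):
            raise ValueError("terminal resistances must be positive")
        if self.bed_pressure_mmhg >= min(self.inlet_pressures_mmhg.values()):
            raise ValueError("bed pressure must lie below every inlet pressure")

    def with_bed_pressure(self, p0: float) -> "BoundaryConditions":
        return BoundaryConditions(
            inlet_pressures_mmhg=self.inlet_pressures_mmhg,
            terminal_resistances=self.terminal_resistances,
            bed_pressure_mmhg=p0,
            nominal_total_flow_ml_min=self.nominal_total_flow_ml_min,
            cortical_drop_mmhg=self.cortical_drop_mmhg,
            viscosity_pa_s=self.viscosity_pa_s,
        )


def compute_terminal_resistances(
    terminal_areas_mm2: dict,
    total_area_mm2: float,
    inlet_nodes=None,
    inlet_pressure_mmhg: float = DEFAULT_INLET_PRESSURE_MMHG,
    total_flow_ml_min: float = DEFAULT_TOTAL_FLOW_ML_MIN,
    cortical_drop_mmhg: float = DEFAULT_CORTICAL_DROP_MMHG,
    bed_pressure_mmhg: float = 0.0,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
) -> BoundaryConditions:
    """Per-terminal resistances from areal flow shares.

    Nominal terminal flow q_i = Q_total area_i / area_total, and
    R_i = cortical_drop / q_i, so the nominal flows sum exactly to the
    total cerebral flow.
    """
    if any(a <= 0 for a in terminal_areas_mm2.values()):
        raise ValueError("terminal areas must be positive")
    resistances = {}
    for node, area in terminal_areas_mm2.items():
        q_i = total_flow_ml_min * area / total_area_mm2
        resistances[int(node)] = cortical_drop_mmhg / q_i
    inlet_pressures = {int(n): inlet_pressure_mmhg for n in (inlet_nodes or [0])}
    return BoundaryConditions(
        inlet_pressures_mmhg=inlet_pressures,
        terminal_resistances=resistances,
        bed_pressure_mmhg=bed_pressure_mmhg,
        nominal_total_flow_ml_min=total_flow_ml_min,
        cortical_drop_mmhg=cortical_drop_mmhg,
        viscosity_pa_s=viscosity_pa_s,
    )


@dataclass
class FlowSolution:
    """Nodal pressures (mmHg), signed edge flows (mL/min, positive from
    source to target) and solver diagnostics."""

    pressures_mmhg: np.ndarray
    flows_ml_min: np.ndarray
    residual_norm: float
    method: str
    iterations: int = 0


class SingularSystemError(RuntimeError):
    pass


class FlowSystem:
    """Assembled linear system for one network + boundary conditions.

    The reduced unknowns are all non-inlet nodes; Robin terminals add a
    diagonal conductance 1/R_i and a right-hand-side term p_0 / R_i.
    ``solve`` supports exact low-rank conductance updates (edge scaling
    or added edges) against a single factorization.
    """

    def __init__(self, net: VascularNetwork, bcs: BoundaryConditions):
        self.net = net
        self.bcs = bcs
        n = net.n_nodes
        self.is_dirichlet = np.zeros(n, dtype=bool)
        self.dirichlet_pa = np.zeros(n)
        for node, p in bcs.inlet_pressures_mmhg.items():
            self.is_dirichlet[node] = True
            self.dirichlet_pa[node] = units.mmhg_to_pa(p)
        self.unknown_index = np.full(n, -1, dtype=np.int64)
        unknowns = np.flatnonzero(~self.is_dirichlet)
        self.unknown_index[unknowns] = np.arange(len(unknowns))
        self.unknown_nodes = unknowns
        self.n_unknowns = len(unknowns)

        self.k = edge_conductance(
            net.edge_diameter_um, net.edge_length_um, bcs.viscosity_pa_s
        )

        self.term_nodes = np.array(sorted(bcs.terminal_resistances), dtype=np.int64)
        self.term_g = np.array(
            [
                1.0 / (bcs.terminal_resistances[int(t)] * units.RESISTANCE_TO_SI)
                for t in self.term_nodes
            ]
        )
        self.p0_pa = units.mmhg_to_pa(bcs.bed_pressure_mmhg)
        self._check_solvable()
        self._assemble()
        self._lu = None

    # -- assembly ------------------------------------------------------
    def _check_solvable(self):
        net = self.net
        g = coo_matrix(
            (np.ones(net.n_edges), (net.edge_source, net.edge_target)),
            shape=(net.n_nodes, net.n_nodes),
        )
        n_comp, comp = connected_components(g, directed=False)
        grounded = set(comp[self.is_dirichlet]) | set(comp[self.term_nodes])
        bad = [c for c in range(n_comp) if c not in grounded]
        if bad:
            sizes = np.bincount(comp)
            raise SingularSystemError(
                "floating subgraph(s) without any pressure boundary: "
                f"components {[(int(c), int(sizes[c])) for c in bad[:10]]}"
            )

    def _assemble(self):
        net, k = self.net, self.k
        ui = self.unknown_index
        s, t = net.edge_source, net.edge_target
        su, tu = ui[s], ui[t]
        rows, cols, vals = [], [], []
        b = np.zeros(self.n_unknowns)

        both = (su >= 0) & (tu >= 0)
        rows.extend([su[both], tu[both], su[both], tu[both]])
        cols.extend([su[both], tu[both], tu[both], su[both]])
        vals.extend([k[both], k[both], -k[both], -k[both]])

        for here, there in ((su, t), (tu, s)):
            m = (here >= 0) & self.is_dirichlet[there]
            rows.append(here[m])
            cols.append(here[m])
            vals.append(k[m])
            np.add.at(b, here[m], k[m] * self.dirichlet_pa[there[m]])

        tr = ui[self.term_nodes]
        rows.append(tr)
        cols.append(tr)
        vals.append(self.term_g)
        np.add.at(b, tr, self.term_g * self.p0_pa)

        self.matrix = csc_matrix(
            coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n_unknowns, self.n_unknowns),
            )
        )
        self.rhs = b

    # -- low-rank updates ---------------------------------------------
    def _update_vectors(self, updates):
        """Translate edge conductance edits into (U, c, delta_b).

        Each update is (node_u, node_v, delta_k).  Returns U (n x m),
        coefficient vector c and the RHS correction, or (None, None, db)
        when every touched node is Dirichlet.
        """
        cols, coeffs = [], []
        db = np.zeros(self.n_unknowns)
        ui = self.unknown_index
        for u, v, dk in updates:
            iu, iv = ui[u], ui[v]
            if dk == 0.0 or (iu < 0 and iv < 0):
                continue
            vec = np.zeros(self.n_unknowns)
            if iu >= 0 and iv >= 0:
                vec[iu] = 1.0
                vec[iv] = -1.0
            elif iu >= 0:
                vec[iu] = 1.0
                db[iu] += dk * self.dirichlet_pa[v]
            else:
                vec[iv] = 1.0
                db[iv] += dk * self.dirichlet_pa[u]
            cols.append(vec)
            coeffs.append(dk)
        if not cols:
            return None, None, db
        return np.column_stack(cols), np.asarray(coeffs), db

    def factorize(self):
        if self._lu is None:
            self._lu = splu(self.matrix)
        return self._lu

    def solve_reduced(self, updates=None):
        """Reduced-system solve, optionally with conductance updates
        applied through the Woodbury identity against the cached
        factorization."""
        lu = self.factorize()
        rhs = self.rhs
        if not updates:
            return lu.solve(rhs)
        U, c, db = self._update_vectors(updates)
        rhs = rhs + db
        y = lu.solve(rhs)
        if U is None:
            return y
        Z = lu.solve(U)
        S = np.diag(1.0 / c) + U.T @ Z
        alpha = np.linalg.solve(S, U.T @ y)
        return y - Z @ alpha

    # -- full solves ---------------------------------------------------
    def full_pressures_pa(self, reduced: np.ndarray) -> np.ndarray:
        p = self.dirichlet_pa.copy()
        p[self.unknown_nodes] = reduced
        return p

    def edge_flows_ml_min(self, p_pa: np.ndarray, k=None) -> np.ndarray:
        k = self.k if k is None else k
        dq = k * (p_pa[self.net.edge_source] - p_pa[self.net.edge_target])
        return units.m3_s_to_ml_min(dq)

    def terminal_outflows_ml_min(self, p_pa: np.ndarray) -> np.ndarray:
        """Outflow q_i = (p_i - p_0) / R_i at each Robin terminal,
        aligned with ``term_nodes``."""
        q = self.term_g * (p_pa[self.term_nodes] - self.p0_pa)
        return units.m3_s_to_ml_min(q)

    def total_inflow_ml_min(self, p_pa: np.ndarray, k=None) -> float:
        k = self.k if k is None else k
        s, t = self.net.edge_source, self.net.edge_target
        q = k * (p_pa[s] - p_pa[t])
        total = q[self.is_dirichlet[s]].sum() - q[self.is_dirichlet[t]].sum()
        return units.m3_s_to_ml_min(total)


def assemble_and_solve(
    net: VascularNetwork,
    bcs: BoundaryConditions,
    solver: str = "auto",
    tol: float = 1e-10,
) -> FlowSolution:
    """Assemble the nodal pressure system and solve it.

    ``solver``: "direct" (sparse LU), "iterative" (ILU-preconditioned
    conjugate gradient on the SPD reduced system) or "auto" (direct up
    to 50,000 unknowns, iterative beyond).
    """
    sys_ = FlowSystem(net, bcs)
    if solver == "auto":
        solver = "direct" if sys_.n_unknowns <= DIRECT_SOLVER_LIMIT else "iterative"
    iterations = 0
    if solver == "direct":
        reduced = sys_.solve_reduced()
    elif solver == "iterative":
        ilu = spilu(sys_.matrix, drop_tol=1e-5, fill_factor=20)
        M = LinearOperator(sys_.matrix.shape, ilu.solve)
        count = [0]

        def _cb(_):
            count[0] += 1

        reduced, info = cg(
            sys_.matrix, sys_.rhs, rtol=tol, maxiter=5000, M=M, callback=_cb
        )
        iterations = count[0]
        if info != 0:
            raise RuntimeError(
                f"iterative solver did not converge (info={info}, "
                f"iterations={iterations})"
            )
    else:
        raise ValueError(f"unknown solver {solver!r}")

    res = sys_.matrix @ reduced - sys_.rhs
    rhs_norm = np.linalg.norm(sys_.rhs)
    residual = float(np.linalg.norm(res) / (rhs_norm if rhs_norm > 0 else 1.0))
    if residual > max(tol * 1e4, 1e-8):
        raise RuntimeError(f"solver residual too large: {residual:.3e}")
    p_pa = sys_.full_pressures_pa(reduced)
    return FlowSolution(
        pressures_mmhg=units.pa_to_mmhg(p_pa),
        flows_ml_min=sys_.edge_flows_ml_min(p_pa),
        residual_norm=residual,
        method=solver,
        iterations=iterations,
    )


# ----------------------------------------------------------------------
# diagnostics


@dataclass
class MassBalanceReport:
    max_interior_imbalance_rel: float
    total_inflow_ml_min: float
    total_outflow_ml_min: float
    global_imbalance_rel: float


def check_mass_balance(
    net: VascularNetwork, bcs: BoundaryConditions, sol: FlowSolution
) -> MassBalanceReport:
    """Per-node conservation check and global inflow/outflow summary."""
    q = sol.flows_ml_min
    net_flux = np.zeros(net.n_nodes)
    np.subtract.at(net_flux, net.edge_source, q)
    np.add.at(net_flux, net.edge_target, q)
    # at Robin terminals the imbalance is the outflow to the bed
    term_nodes = np.array(sorted(bcs.terminal_resistances), dtype=np.int64)
    p = sol.pressures_mmhg
    term_q = (p[term_nodes] - bcs.bed_pressure_mmhg) / np.array(
        [bcs.terminal_resistances[int(t)] for t in term_nodes]
    )
    net_flux[term_nodes] -= term_q
    interior = np.ones(net.n_nodes, dtype=bool)
    interior[list(bcs.inlet_pressures_mmhg)] = False

    inflow = float(net_flux[~interior].sum() * -1.0)
    outflow = float(term_q.sum())
    scale = max(abs(inflow), 1e-30)
    return MassBalanceReport(
        max_interior_imbalance_rel=float(np.abs(net_flux[interior]).max() / scale),
        total_inflow_ml_min=inflow,
        total_outflow_ml_min=outflow,
        global_imbalance_rel=float(abs(inflow - outflow) / scale),
    )


def total_inflow_ml_min(
    net: VascularNetwork, bcs: BoundaryConditions, sol: FlowSolution
) -> float:
    q = sol.flows_ml_min
    s, t = net.edge_source, net.edge_target
    inlet = np.zeros(net.n_nodes, dtype=bool)
    inlet[list(bcs.inlet_pressures_mmhg)] = True
    return float(q[inlet[s]].sum() - q[inlet[t]].sum())


def terminal_outflows(
    net: VascularNetwork, bcs: BoundaryConditions, sol: FlowSolution
) -> dict:
    """Map penetrating-terminal node id -> outflow (mL/min)."""
    out = {}
    p = sol.pressures_mmhg
    for node, r in bcs.terminal_resistances.items():
        out[int(node)] = float((p[node] - bcs.bed_pressure_mmhg) / r)
    return out


# ----------------------------------------------------------------------
# bed-pressure calibration


def calibrate_bed_pressure(
    net: VascularNetwork,
    bcs: BoundaryConditions,
    target_total_flow_ml_min: float = DEFAULT_TOTAL_FLOW_ML_MIN,
    tolerance_ml_min: float = 1.0,
    solver: str = "auto",
) -> BoundaryConditions:
    """Choose the vascular-bed pressure p_0 so the normal-condition
    total inflow hits the target.

    Total inflow is affine and strictly decreasing in p_0 (linearity of
    the network), so two solves identify the exact root; the result is
    verified with a third solve.  Raises if the target is outside the
    range achievable with p_0 in [0, min inlet pressure).
    """
    p_min = min(bcs.inlet_pressures_mmhg.values())
    probes = [0.0, 0.5 * p_min]
    flows = []
    for p0 in probes:
        sol = assemble_and_solve(net, bcs.with_bed_pressure(p0), solver=solver)
        flows.append(total_inflow_ml_min(net, bcs, sol))
    slope = (flows[1] - flows[0]) / (probes[1] - probes[0])
    if slope >= 0:
        raise RuntimeError("total inflow is not decreasing in p_0")
    p0_star = probes[0] + (target_total_flow_ml_min - flows[0]) / slope
    q_at_pmin = flows[0] + slope * p_min
    if not 0.0 <= p0_star < p_min:
        raise ValueError(
            f"target {target_total_flow_ml_min} mL/min unreachable; achievable "
            f"range is ({q_at_pmin:.3f}, {flows[0]:.3f}] mL/min for p_0 in "
            f"[0, {p_min}) mmHg"
        )
    calibrated = bcs.with_bed_pressure(float(p0_star))
    sol = assemble_and_solve(net, calibrated, solver=solver)
    achieved = total_inflow_ml_min(net, calibrated, sol)
    if abs(achieved - target_total_flow_ml_min) > tolerance_ml_min:
        raise RuntimeError(
            f"calibration verification failed: achieved {achieved:.3f} mL/min"
        )
    return calibrated
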