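"""Poiseuille network solver: closed forms, conservation, maximum
principle, solver agreement, monotonicity and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cerebroflow import flow as F
from cerebroflow import units
from cerebroflow.network import VascularNetwork

from conftest import (
    random_grounded_network,
    series_network,
    single_edge_network,
    symmetric_y_network,
)


def _bcs(net, resistances, p0=10.0):
    return F.BoundaryConditions(
        inlet_pressures_mmhg={0: 100.0},
        terminal_resistances=resistances,
        bed_pressure_mmhg=p0,
    )


class TestConductance:
    def test_hand_value_40um_1mm(self):
        # pi (4e-5)^4 / (128 * 3.5e-3 * 1e-3)
        k = F.edge_conductance(40.0, 1000.0, 3.5e-3)
        assert k == pytest.approx(1.7952e-14, rel=1e-4)

    def test_fourth_power_scaling(self):
        assert F.edge_conductance(80.0, 1000.0) == pytest.approx(
            16.0 * F.edge_conductance(40.0, 1000.0), rel=1e-12
        )

    def test_rejects_nonpositive(self):
        for d, L in [(0, 1), (1, 0), (-1, 1)]:
            with pytest.raises(ValueError):
                F.edge_conductance(d, L)


class TestTerminalResistances:
    def test_one_percent_area_hand_values(self):
        bcs = F.compute_terminal_resistances(
            {5: 1.0, 6: 99.0}, 100.0, inlet_nodes=[0]
        )
        # q = 715 * 0.01 = 7.15 mL/min; R = 65 / 7.15
        assert bcs.terminal_resistances[5] == pytest.approx(65.0 / 7.15, rel=1e-12)

    def test_uniform_areas_equal_resistances(self):
        bcs = F.compute_terminal_resistances(
            {i: 2.5 for i in range(1, 5)}, 10.0, inlet_nodes=[0]
        )
        rs = set(round(r, 12) for r in bcs.terminal_resistances.values())
        assert len(rs) == 1

    def test_nominal_flows_sum_to_total(self):
        areas = {i: a for i, a in enumerate(np.linspace(1, 7, 20), start=1)}
        total = sum(areas.values())
        bcs = F.compute_terminal_resistances(areas, total, inlet_nodes=[0])
        q = sum(bcs.cortical_drop_mmhg / r for r in bcs.terminal_resistances.values())
        assert q == pytest.approx(715.0, rel=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            F.compute_terminal_resistances({1: 0.0}, 1.0, inlet_nodes=[0])


class TestClosedForms:
    def test_single_edge_series_resistance(self):
        net = single_edge_network(diameter_um=100.0, length_um=10_000.0)
        R_robin = 9.0909
        bcs = _bcs(net, {1: R_robin}, p0=20.0)
        sol = F.assemble_and_solve(net, bcs, solver="direct")
        k_si = F.edge_conductance(100.0, 10_000.0)
        # edge resistance in mmHg.min/mL
        r_edge = 1.0 / (k_si / units.RESISTANCE_FROM_SI) / 1.0
        r_edge = units.RESISTANCE_FROM_SI / k_si
        q_expected = (100.0 - 20.0) / (r_edge + R_robin)
        assert sol.flows_ml_min[0] == pytest.approx(q_expected, rel=1e-12)

    def test_two_segments_in_series_halve_the_flow(self):
        one = single_edge_network()
        two = series_network(2)
        bcs1 = _bcs(one, {1: 1e-6}, p0=0.0)
        bcs2 = _bcs(two, {2: 1e-6}, p0=0.0)
        q1 = F.assemble_and_solve(one, bcs1).flows_ml_min[0]
        q2 = F.assemble_and_solve(two, bcs2).flows_ml_min[0]
        assert q2 == pytest.approx(q1 / 2.0, rel=1e-6)

    def test_symmetric_y_splits_evenly(self):
        net = symmetric_y_network()
        bcs = _bcs(net, {2: 5.0, 3: 5.0})
        sol = F.assemble_and_solve(net, bcs)
        assert sol.flows_ml_min[1] == pytest.approx(
            sol.flows_ml_min[0] / 2.0, rel=1e-12
        )
        assert sol.flows_ml_min[2] == pytest.approx(
            sol.flows_ml_min[1], rel=1e-12
        )

    def test_parallel_edges_add_conductance(self):
        # two identical parallel paths double the flow of one
        def _net(n_par):
            net = VascularNetwork()
            net.add_nodes([[0, 0, 0], [10, 0, 0]], "junction")
            net.node_role[0] = "inlet"
            net.node_role[1] = "penetrating_terminal"
            for _ in range(n_par):
                net.add_edges([0], [1], [100.0], [10_000.0], "pial")
            return net

        q1 = F.assemble_and_solve(_net(1), _bcs(_net(1), {1: 1e-6}, 0.0)).flows_ml_min.sum()
        q2 = F.assemble_and_solve(_net(2), _bcs(_net(2), {1: 1e-6}, 0.0)).flows_ml_min.sum()
        assert q2 == pytest.approx(2.0 * q1, rel=1e-6)


class TestConservationAndBounds:
    def test_mass_balance_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            net, bcs = random_grounded_network(rng)
            sol = F.assemble_and_solve(net, bcs, solver="direct")
            rep = F.check_mass_balance(net, bcs, sol)
            assert rep.max_interior_imbalance_rel <= 1e-8
            assert rep.global_imbalance_rel <= 1e-8

    def test_discrete_maximum_principle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            net, bcs = random_grounded_network(rng)
            sol = F.assemble_and_solve(net, bcs, solver="direct")
            p = sol.pressures_mmhg
            assert p.max() <= 100.0 + 1e-9
            assert p.min() >= bcs.bed_pressure_mmhg - 1e-9

    def test_perturbed_pressure_breaks_balance(self):
        net = series_network(3)
        bcs = _bcs(net, {3: 10.0}, p0=0.0)
        sol = F.assemble_and_solve(net, bcs)
        sol.pressures_mmhg[1] += 1.0
        p_pa = units.mmhg_to_pa(sol.pressures_mmhg)
        sys_ = F.FlowSystem(net, bcs)
        flows = sys_.edge_flows_ml_min(p_pa)
        imbalance = flows[0] - flows[1]
        assert abs(imbalance) > 1e-6

    def test_floating_subgraph_raises(self):
        net = series_network(2)
        net.add_nodes([[99, 99, 0], [100, 99, 0]], "junction")
        net.add_edges([3], [4], [50.0], [1000.0], "pial")
        with pytest.raises(F.SingularSystemError):
            F.assemble_and_solve(net, _bcs(net, {2: 10.0}))


class TestSolverAgreement:
    def test_direct_matches_dense_and_iterative(self):
        rng = np.random.default_rng(2)
        net, bcs = random_grounded_network(rng, n_nodes=200, extra_edges=80)
        sol_d = F.assemble_and_solve(net, bcs, solver="direct")
        sol_i = F.assemble_and_solve(net, bcs, solver="iterative")
        assert np.allclose(
            sol_d.pressures_mmhg, sol_i.pressures_mmhg, rtol=1e-8, atol=1e-8
        )
        # independent dense oracle
        sys_ = F.FlowSystem(net, bcs)
        dense = np.linalg.solve(sys_.matrix.toarray(), sys_.rhs)
        reduced = sol_d.pressures_mmhg[sys_.unknown_nodes] * units.MMHG_TO_PA
        assert np.allclose(dense, reduced, rtol=1e-8)

    def test_residual_reported(self):
        net = series_network(4)
        sol = F.assemble_and_solve(net, _bcs(net, {4: 10.0}))
        assert sol.residual_norm < 1e-10


class TestLinearityAndMonotonicity:
    def test_scaling_driving_pressures_scales_flows(self):
        net = symmetric_y_network()
        bcs1 = _bcs(net, {2: 5.0, 3: 5.0}, p0=10.0)
        sol1 = F.assemble_and_solve(net, bcs1)
        # double every boundary pressure -> flows double
        bcs2 = F.BoundaryConditions(
            inlet_pressures_mmhg={0: 200.0},
            terminal_resistances={2: 5.0, 3: 5.0},
            bed_pressure_mmhg=20.0,
        )
        sol2 = F.assemble_and_solve(net, bcs2)
        assert np.allclose(sol2.flows_ml_min, 2.0 * sol1.flows_ml_min, rtol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rayleigh_monotonicity(self, seed):
        """Adding an edge never decreases total inflow at fixed BCs."""
        rng = np.random.default_rng(seed)
        net, bcs = random_grounded_network(rng, n_nodes=25, extra_edges=5)
        base = F.assemble_and_solve(net, bcs, solver="direct")
        q0 = F.total_inflow_ml_min(net, bcs, base)
        # add one random new edge
        a, b = 0, 0
        existing = {(min(s, t), max(s, t))
                    for s, t in zip(net.edge_source, net.edge_target)}
        while a == b or (min(a, b), max(a, b)) in existing:
            a, b = int(rng.integers(0, net.n_nodes)), int(rng.integers(0, net.n_nodes))
        net2 = net.copy()
        net2.add_edges([a], [b], [150.0], [5000.0], "pial")
        q1 = F.total_inflow_ml_min(net2, bcs, F.assemble_and_solve(net2, bcs, solver="direct"))
        assert q1 >= q0 - 1e-9 * max(1.0, abs(q0))

    def test_increasing_a_diameter_never_decreases_inflow(self):
        rng = np.random.default_rng(3)
        net, bcs = random_grounded_network(rng)
        q0 = F.total_inflow_ml_min(net, bcs, F.assemble_and_solve(net, bcs))
        net2 = net.copy()
        net2.edge_diameter_um[5] *= 2.0
        q1 = F.total_inflow_ml_min(net2, bcs, F.assemble_and_solve(net2, bcs))
        assert q1 >= q0 - 1e-9 * abs(q0)


class TestWoodburyUpdates:
    def test_low_rank_update_matches_full_reassembly(self):
        rng = np.random.default_rng(4)
        net, bcs = random_grounded_network(rng, n_nodes=40, extra_edges=12)
        sys_ = F.FlowSystem(net, bcs)
        # add an edge between two interior nodes via the update path
        u, v, d, L = 3, 17, 120.0, 4000.0
        k_new = float(F.edge_conductance(d, L, bcs.viscosity_pa_s))
        p_upd = sys_.full_pressures_pa(sys_.solve_reduced([(u, v, k_new)]))
        net2 = net.copy()
        net2.add_edges([u], [v], [d], [L], "pial")
        sol2 = F.assemble_and_solve(net2, bcs, solver="direct")
        assert np.allclose(
            units.pa_to_mmhg(p_upd), sol2.pressures_mmhg, rtol=1e-9, atol=1e-9
        )

    def test_update_touching_dirichlet_node(self):
        rng = np.random.default_rng(5)
        net, bcs = random_grounded_network(rng, n_nodes=30)
        sys_ = F.FlowSystem(net, bcs)
        # scale the conductance of an inlet-incident edge down 99%^4
        e = int(np.flatnonzero(net.edge_source == 0)[0])
        k_e = float(
            F.edge_conductance(
                net.edge_diameter_um[e], net.edge_length_um[e], bcs.viscosity_pa_s
            )
        )
        scale = 0.01**4
        upd = [(int(net.edge_source[e]), int(net.edge_target[e]), k_e * (scale - 1))]
        p_upd = sys_.full_pressures_pa(sys_.solve_reduced(upd))
        net2 = net.copy()
        net2.edge_diameter_um[e] *= 0.01
        sol2 = F.assemble_and_solve(net2, bcs, solver="direct")
        assert np.allclose(
            units.pa_to_mmhg(p_upd), sol2.pressures_mmhg, rtol=1e-8, atol=1e-8
        )


class TestCalibration:
    def _headroom_network(self, n_terms=50):
        """Fat arterial feed into n_terms Robin terminals sized so the
        full 715 mL/min is reachable with room to spare."""
        net = VascularNetwork()
        net.add_nodes([[0, 0, 0], [20, 0, 0]], "junction")
        net.node_role[0] = "inlet"
        term_pos = [[40, i, 0] for i in range(n_terms)]
        terms = net.add_nodes(term_pos, "penetrating_terminal")
        net.add_edges([0], [1], [3000.0], [20_000.0], "stub")
        net.add_edges(
            [1] * n_terms, terms, 800.0, 20_000.0, "pial"
        )
        areas = {int(t): 1.0 for t in terms}
        bcs = F.compute_terminal_resistances(
            areas, float(n_terms), inlet_nodes=[0]
        )
        return net, bcs

    def test_calibration_reaches_715(self):
        net, bcs = self._headroom_network()
        cal = F.calibrate_bed_pressure(net, bcs, 715.0, tolerance_ml_min=1.0)
        sol = F.assemble_and_solve(net, cal)
        assert F.total_inflow_ml_min(net, cal, sol) == pytest.approx(715.0, abs=1.0)
        assert 0.0 <= cal.bed_pressure_mmhg < 100.0

    def test_single_edge_calibration_closed_form(self):
        net = single_edge_network(diameter_um=500.0, length_um=20_000.0)
        areas = {1: 1.0}
        bcs = F.compute_terminal_resistances(areas, 1.0, inlet_nodes=[0])
        R_robin = bcs.terminal_resistances[1]
        r_edge = units.RESISTANCE_FROM_SI / F.edge_conductance(500.0, 20_000.0)
        target = 10.0
        p0_expected = 100.0 - target * (r_edge + R_robin)
        cal = F.calibrate_bed_pressure(net, bcs, target, tolerance_ml_min=1e-6)
        assert cal.bed_pressure_mmhg == pytest.approx(p0_expected, abs=1e-6)

    def test_vanishing_driving_pressure_kills_flow(self):
        net = single_edge_network()
        bcs = _bcs(net, {1: 10.0}, p0=100.0 - 1e-9)
        sol = F.assemble_and_solve(net, bcs)
        assert abs(sol.flows_ml_min[0]) < 1e-9

    def test_unreachable_target_reports_range(self):
        net = single_edge_network(diameter_um=30.0)  # very resistive
        bcs = F.compute_terminal_resistances({1: 1.0}, 1.0, inlet_nodes=[0])
        with pytest.raises(ValueError, match="achievable"):
            F.calibrate_bed_pressure(net, bcs, 715.0)
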