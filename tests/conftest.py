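"""Shared fixtures: small meshes, toy networks and the scaled
whole-network build used by the acceptance-level tests.

Everything is generated programmatically and cached at module/session
scope so the suite stays within a few minutes on one CPU.
"""

import numpy as np
import pytest

from cerebroflow import (
    BoundaryConditions,
    OcclusionSpec,
    boundary_conditions_for,
    build_network,
    generate_seed_arteries,
    generate_synthetic_cortex,
    scaled_fixture_config,
    smoke_config,
)
from cerebroflow.network import VascularNetwork


@pytest.fixture(scope="session")
def sphere_mesh():
    """5120-triangle sphere of radius 60 mm."""
    return generate_synthetic_cortex(5120, semi_axes=(60.0, 60.0, 60.0), seed=1)


@pytest.fixture(scope="session")
def small_sphere_mesh():
    """1280-triangle sphere for cheap partitioning tests."""
    return generate_synthetic_cortex(1280, semi_axes=(60.0, 60.0, 60.0), seed=1)


@pytest.fixture(scope="session")
def sphere_seeds(sphere_mesh):
    return generate_seed_arteries(sphere_mesh, seed=1)


@pytest.fixture(scope="session")
def smoke_build():
    """Minimal end-to-end network (sphere, N1=12, N2=3)."""
    return build_network(smoke_config(seed=0))


@pytest.fixture(scope="session")
def smoke_bcs(smoke_build):
    return boundary_conditions_for(smoke_build)


@pytest.fixture(scope="session")
def fixture_build():
    """The scaled whole-network fixture: sphere cortex, N1=200, N2=10,
    ~20k pial nodes, seed 1."""
    return build_network(scaled_fixture_config(seed=1))


@pytest.fixture(scope="session")
def fixture_bcs(fixture_build):
    return boundary_conditions_for(fixture_build)


# ----------------------------------------------------------------------
# tiny hand-built networks


def single_edge_network(diameter_um=100.0, length_um=10_000.0):
    """Inlet -> Robin terminal through one vessel."""
    net = VascularNetwork()
    net.add_nodes([[0, 0, 0], [10, 0, 0]], "inlet")
    net.node_role[1] = "penetrating_terminal"
    net.add_edges([0], [1], [diameter_um], [length_um], "pial")
    return net


def series_network(n_segments, diameter_um=100.0, segment_um=10_000.0):
    net = VascularNetwork()
    pos = [[i * segment_um * 1e-3, 0, 0] for i in range(n_segments + 1)]
    net.add_nodes(pos, "junction")
    net.node_role[0] = "inlet"
    net.node_role[n_segments] = "penetrating_terminal"
    net.add_edges(
        list(range(n_segments)),
        list(range(1, n_segments + 1)),
        diameter_um,
        segment_um,
        "pial",
    )
    return net


def symmetric_y_network():
    net = VascularNetwork()
    net.add_nodes(
        [[0, 0, 0], [5, 0, 0], [10, 3, 0], [10, -3, 0]], "junction"
    )
    net.node_role[0] = "inlet"
    net.node_role[2] = "penetrating_terminal"
    net.node_role[3] = "penetrating_terminal"
    net.add_edges([0, 1, 1], [1, 2, 3], [200, 120, 120], [5000, 6000, 6000], "pial")
    return net


def random_grounded_network(rng, n_nodes=30, extra_edges=10):
    """Random spanning tree plus chords; node 0 is the inlet and the
    last five nodes are Robin terminals."""
    pos = rng.uniform(0, 50, size=(n_nodes, 3))
    net = VascularNetwork()
    net.add_nodes(pos, "junction")
    net.node_role[0] = "inlet"
    terminals = list(range(n_nodes - 5, n_nodes))
    for t in terminals:
        net.node_role[t] = "penetrating_terminal"
    src, dst = [], []
    for i in range(1, n_nodes):
        src.append(int(rng.integers(0, i)))
        dst.append(i)
    seen = {(min(s, d), max(s, d)) for s, d in zip(src, dst)}
    while extra_edges > 0:
        a, b = int(rng.integers(0, n_nodes)), int(rng.integers(0, n_nodes))
        if a == b or (min(a, b), max(a, b)) in seen:
            continue
        seen.add((min(a, b), max(a, b)))
        src.append(a)
        dst.append(b)
        extra_edges -= 1
    n_e = len(src)
    net.add_edges(
        src,
        dst,
        rng.uniform(60, 300, n_e),
        rng.uniform(2000, 20000, n_e),
        "pial",
    )
    bcs = BoundaryConditions(
        inlet_pressures_mmhg={0: 100.0},
        terminal_resistances={t: float(rng.uniform(50, 500)) for t in terminals},
        bed_pressure_mmhg=10.0,
    )
    return net, bcs
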