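"""Tiered arterial anastomoses.

Tier 2 — intermediate anastomoses: sparse O(10^2) um vessels bridging
coarse-tree terminals of adjacent main-artery territories.  Candidate
pairs are formed from every coarse terminal whose region touches the
other territory, paired with its nearest counterpart; the anastomosis
diameter is the arithmetic mean of the two connecting terminal branches.

Tier 3 — pial network: a dense idealized loop network built as the dual
graph of the surface triangulation (one node per triangle at its
centroid, one edge per shared triangle edge).  On a closed mesh every
pial node has exactly three neighbors and the dual faces around
degree-6 vertices are hexagons, mimicking the observed hexagonal-loop
idealization of pial arterioles.  A penetrating arteriole hangs off
every pial node and ends in the network's terminal outlets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh
from .network import (
    KIND_ANASTOMOSIS,
    KIND_CONNECTOR,
    KIND_PENETRATING,
    KIND_PIAL,
    ROLE_COARSE_TERMINAL,
    ROLE_FINE_TERMINAL,
    ROLE_INLET,
    ROLE_PENETRATING_TERMINAL,
    ROLE_PIAL,
    VascularNetwork,
)


@dataclass
class AnastomosisCandidate:
    """A potential intermediate anastomosis between two coarse terminals."""

    candidate_id: int
    terminal_a: int
    terminal_b: int
    territory_a: str
    territory_b: str
    separation_mm: float
    diameter_um: float
    adopted: bool = False


@dataclass
class PialNetworkParams:
    """Pial-layer parameters: 40 um pial and penetrating diameters at the
    physiological penetrating-artery surface density of 8.7 /mm^2.

    When the mesh is coarser than the target density (scaled-down runs),
    each modeled vessel stands in for ``s = target/actual`` real ones.
    With ``density_compensation`` on (default) diameters are widened to
    keep the bed hydraulically equivalent to the fully resolved layer:
    the parallel penetrating bed preserves its total conductance with
    d_pen * s^(3/8) (edge lengths already grow as sqrt(s) with the
    mesh), and the pial sheet preserves its per-square sheet conductance
    with d_pial * s^(1/8).
    """

    pial_diameter_um: float = 40.0
    penetrating_diameter_um: float = 40.0
    target_density_per_mm2: float = 8.7
    density_compensation: bool = True

    def __post_init__(self):
        if min(
            self.pial_diameter_um,
            self.penetrating_diameter_um,
            self.target_density_per_mm2,
        ) <= 0:
            raise ValueError("pial parameters must be positive")

    def lumping_factor(self, mesh: "SurfaceMesh") -> float:
        """How many real penetrating arteries each pial node lumps."""
        actual = mesh.n_triangles / mesh.total_area
        return max(1.0, self.target_density_per_mm2 / actual)

    def effective_pial_diameter_um(self, mesh: "SurfaceMesh") -> float:
        if not self.density_compensation:
            return self.pial_diameter_um
        return self.pial_diameter_um * self.lumping_factor(mesh) ** 0.125

    def effective_penetrating_diameter_um(self, mesh: "SurfaceMesh") -> float:
        if not self.density_compensation:
            return self.penetrating_diameter_um
        return self.penetrating_diameter_um * self.lumping_factor(mesh) ** 0.375


def terminal_edge_diameters(net: VascularNetwork, role: str) -> dict:
    """Map terminal node id -> diameter (um) of the tree edge ending there."""
    out = {}
    terminals = set(int(i) for i in net.nodes_with_role(role))
    for e in range(net.n_edges):
        for node in (int(net.edge_source[e]), int(net.edge_target[e])):
            if node in terminals:
                out[node] = float(net.edge_diameter_um[e])
    return out


# ----------------------------------------------------------------------
# Tier 2: intermediate anastomoses


def _region_adjacency(mesh: SurfaceMesh, region_of_triangle: np.ndarray) -> set:
    fa = mesh.face_adjacency
    ra, rb = region_of_triangle[fa[:, 0]], region_of_triangle[fa[:, 1]]
    mask = (ra != rb) & (ra >= 0) & (rb >= 0)
    pairs = set()
    for x, y in zip(ra[mask], rb[mask]):
        pairs.add((int(min(x, y)), int(max(x, y))))
    return pairs


def find_candidate_pairs(
    net: VascularNetwork,
    mesh: SurfaceMesh,
    region_of_triangle: np.ndarray,
    region_territory: np.ndarray,
    territory_a: str,
    territory_b: str,
) -> list:
    """Candidate intermediate anastomoses between two territories.

    Every coarse terminal of one territory whose region shares a mesh
    edge with a region of the other territory is paired with its nearest
    (3D Euclidean) coarse terminal across the boundary; symmetric
    duplicates are removed and candidates are sorted by separation
    (ascending), ties broken by node ids.
    """
    terminals = net.nodes_with_role(ROLE_COARSE_TERMINAL)
    term_a = terminals[net.node_territory[terminals] == territory_a]
    term_b = terminals[net.node_territory[terminals] == territory_b]
    if len(term_a) == 0 or len(term_b) == 0:
        raise ValueError(
            f"territory {territory_a if len(term_a) == 0 else territory_b} "
            "has no coarse terminals"
        )
    adj = _region_adjacency(mesh, region_of_triangle)
    diam = terminal_edge_diameters(net, ROLE_COARSE_TERMINAL)

    def _boundary_terminals(terms, other_territory):
        other_regions = set(
            int(r) for r in np.flatnonzero(region_territory == other_territory)
        )
        out = []
        for t in terms:
            r = int(net.node_region[t])
            for o in other_regions:
                if (min(r, o), max(r, o)) in adj:
                    out.append(int(t))
                    break
        return out

    pairs = set()
    for terms, others, other_label in (
        (term_a, term_b, territory_b),
        (term_b, term_a, territory_a),
    ):
        boundary = _boundary_terminals(terms, other_label)
        if not boundary:
            continue
        tree = cKDTree(net.positions[others])
        dist, idx = tree.query(net.positions[boundary])
        for t, d, i in zip(boundary, dist, idx):
            u, v = int(t), int(others[i])
            pairs.add((min(u, v), max(u, v)))

    cands = []
    for u, v in pairs:
        sep = float(np.linalg.norm(net.positions[u] - net.positions[v]))
        cands.append(
            (
                sep,
                u,
                v,
                str(net.node_territory[u]),
                str(net.node_territory[v]),
                0.5 * (diam[u] + diam[v]),
            )
        )
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    return [
        AnastomosisCandidate(
            candidate_id=i,
            terminal_a=u,
            terminal_b=v,
            territory_a=ta,
            territory_b=tb,
            separation_mm=sep,
            diameter_um=d,
        )
        for i, (sep, u, v, ta, tb, d) in enumerate(cands)
    ]


def add_intermediate_anastomoses(
    net: VascularNetwork, candidates: list, subset
) -> VascularNetwork:
    """Adopt a subset of candidates: one tier-2 edge each, diameter from
    the candidate, length the straight terminal separation."""
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate adoption of the same candidate")
    by_id = {c.candidate_id: c for c in candidates}
    net = net.copy()
    if not subset:
        return net
    chosen = [by_id[i] for i in subset]
    net.add_edges(
        [c.terminal_a for c in chosen],
        [c.terminal_b for c in chosen],
        [c.diameter_um for c in chosen],
        [max(c.separation_mm * 1.0e3, 1.0) for c in chosen],
        KIND_ANASTOMOSIS,
    )
    return net


# ----------------------------------------------------------------------
# Tier 3: pial network


def build_pial_network(
    mesh: SurfaceMesh,
    params: PialNetworkParams,
    triangle_territory=None,
    triangle_region=None,
    triangle_subregion=None,
) -> VascularNetwork:
    """Dual-graph pial layer of a closed triangulated surface.

    One pial node per triangle (at its centroid) and one pial edge per
    interior mesh edge; a closed mesh with T triangles yields T nodes
    and 3T/2 edges, all of degree 3.  Node labels (territory, region,
    subregion) are inherited from the source triangle when provided.
    """
    mesh.validate_closed()
    pial = VascularNetwork()
    pial.add_nodes(
        mesh.triangle_centroids,
        ROLE_PIAL,
        territory=triangle_territory,
        region=triangle_region,
        subregion=triangle_subregion,
    )
    fa = mesh.face_adjacency
    length = np.linalg.norm(
        mesh.triangle_centroids[fa[:, 1]] - mesh.triangle_centroids[fa[:, 0]], axis=1
    )
    pial.add_edges(
        fa[:, 0],
        fa[:, 1],
        params.effective_pial_diameter_um(mesh),
        np.maximum(length * 1.0e3, 1.0),
        KIND_PIAL,
    )
    return pial


def attach_penetrating_arterioles(
    pial: VascularNetwork, mesh: SurfaceMesh, params: PialNetworkParams
) -> VascularNetwork:
    """One penetrating arteriole per pial node, diving into the cortex.

    The edge length is the mean edge length of the node's source
    triangle (the spacing scale of the penetrating bed); the terminal
    node inherits the triangle's territory/region/subregion labels.
    """
    pial = pial.copy()
    pial_nodes = pial.nodes_with_role(ROLE_PIAL)
    tri = np.arange(len(pial_nodes))  # pial node i <-> triangle i
    lengths_mm = mesh.triangle_mean_edge_lengths[tri]
    normals = np.asarray(mesh._trimesh.face_normals)[tri]
    term_pos = pial.positions[pial_nodes] - normals * lengths_mm[:, None]
    term_ids = pial.add_nodes(
        term_pos,
        ROLE_PENETRATING_TERMINAL,
        territory=pial.node_territory[pial_nodes],
        region=pial.node_region[pial_nodes],
        subregion=pial.node_subregion[pial_nodes],
    )
    pial.add_edges(
        pial_nodes,
        term_ids,
        params.effective_penetrating_diameter_um(mesh),
        np.maximum(lengths_mm * 1.0e3, 1.0),
        KIND_PENETRATING,
    )
    return pial


def combine_networks(a: VascularNetwork, b: VascularNetwork) -> tuple:
    """Disjoint union of two networks; returns (combined, node offset of b)."""
    out = a.copy()
    offset = out.n_nodes
    out.positions = np.vstack([out.positions, b.positions])
    for name in ("node_role", "node_territory"):
        setattr(out, name, np.concatenate([getattr(out, name), getattr(b, name)]))
    for name in ("node_region", "node_subregion"):
        setattr(out, name, np.concatenate([getattr(out, name), getattr(b, name)]))
    out.edge_source = np.concatenate([out.edge_source, b.edge_source + offset])
    out.edge_target = np.concatenate([out.edge_target, b.edge_target + offset])
    for name in ("edge_diameter_um", "edge_length_um", "edge_kind", "edge_tier"):
        setattr(out, name, np.concatenate([getattr(out, name), getattr(b, name)]))
    return out, offset


def connect_tree_terminals_to_pial(
    net: VascularNetwork, pial: VascularNetwork
) -> VascularNetwork:
    """Merge the pial layer into the tree network and join every fine
    terminal to its nearest pial node.

    Connector diameter equals the fine terminal branch diameter; length
    is the Euclidean separation with a 1 um floor.  The combined network
    must be a single component containing all inlets; otherwise an error
    lists the disconnected pieces.
    """
    combined, offset = combine_networks(net, pial)
    fine_terms = combined.nodes_with_role(ROLE_FINE_TERMINAL)
    pial_nodes = combined.nodes_with_role(ROLE_PIAL)
    if len(fine_terms) == 0 or len(pial_nodes) == 0:
        raise ValueError("need both fine terminals and a pial layer to connect")
    diam = terminal_edge_diameters(combined, ROLE_FINE_TERMINAL)
    tree = cKDTree(combined.positions[pial_nodes])
    dist, idx = tree.query(combined.positions[fine_terms])
    combined.add_edges(
        fine_terms,
        pial_nodes[idx],
        [diam[int(t)] for t in fine_terms],
        np.maximum(dist * 1.0e3, 1.0),
        KIND_CONNECTOR,
    )
    _check_connected(combined)
    return combined


def _check_connected(net: VascularNetwork) -> None:
    g = coo_matrix(
        (np.ones(net.n_edges), (net.edge_source, net.edge_target)),
        shape=(net.n_nodes, net.n_nodes),
    )
    n_comp, comp = connected_components(g, directed=False)
    if n_comp > 1:
        inlet_comp = set(comp[net.nodes_with_role(ROLE_INLET)])
        sizes = np.bincount(comp)
        orphans = [
            (int(c), int(sizes[c])) for c in range(n_comp) if c not in inlet_comp
        ]
        raise ValueError(
            f"network is disconnected: {n_comp} components; "
            f"components unreachable from inlets (id, size): {orphans[:10]}"
        )
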