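"""Region-confined arterial tree generation.

The cortical surface is partitioned twice: into N1 coarse subregions
covering the whole cortex, and each coarse subregion into N2 fine
subregions.  A binary coarse tree grows from each territory seed to one
terminal per assigned coarse region; an independent fine tree then grows
from every coarse terminal to one terminal per fine subregion, confined
to its parent region.  Growth follows a simplified constrained
constructive optimization (CCO) scheme: terminals are inserted in a
seeded random order, each connecting to the best of the k nearest
existing segments, with the bifurcation point chosen to minimize a
length-times-flow cost — a proxy for the minimum-energy principle.

Terminal target flows are area shares of the total cerebral flow,
q_i = Q |Omega_i| / |Omega|; they weight growth and Murray diameter
splitting only and play no role in the subsequent flow solve, where
boundary conditions are set independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import ArterialSeedSet, SurfaceMesh, TERRITORIES
from .network import (
    KIND_COARSE,
    KIND_FINE,
    KIND_STUB,
    ROLE_COARSE_TERMINAL,
    ROLE_FINE_TERMINAL,
    ROLE_INLET,
    ROLE_JUNCTION,
    ROLE_SEED,
    VascularNetwork,
)


@dataclass
class RegionPartition:
    """Assignment of a triangle subset to contiguous regions.

    ``triangle_ids`` indexes the parent mesh; ``labels`` (same length)
    holds region ids 0..region_count-1.
    """

    level: str  # "coarse" | "fine"
    triangle_ids: np.ndarray
    labels: np.ndarray
    region_areas: np.ndarray
    parent_region: int | None = None

    @property
    def region_count(self) -> int:
        return len(self.region_areas)

    def region_triangles(self, region: int) -> np.ndarray:
        return self.triangle_ids[self.labels == region]

    def full_assignment(self, n_triangles: int) -> np.ndarray:
        """(T,) array over the whole mesh; -1 outside the subset."""
        out = np.full(n_triangles, -1, dtype=np.int64)
        out[self.triangle_ids] = self.labels
        return out


@dataclass
class TreeGrowthParams:
    """Growth and diameter-assignment parameters.

    total_flow_ml_min: cerebral flow Q distributed over the cortex by
    area (used for growth weighting only).  murray_exponent: gamma in
    d_parent^gamma = d_left^gamma + d_right^gamma.  The terminal
    diameter floor (um) prevents unphysically thin distal vessels.
    """

    total_flow_ml_min: float = 715.0
    murray_exponent: float = 3.0
    terminal_diameter_floor_um: float = 30.0
    cco_candidate_connections: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.total_flow_ml_min <= 0:
            raise ValueError("total flow must be positive")
        if not 2.0 <= self.murray_exponent <= 4.0:
            raise ValueError("murray_exponent must lie in [2, 4]")


# ----------------------------------------------------------------------
# surface partitioning


def partition_surface(
    mesh: SurfaceMesh,
    n_regions: int,
    seed: int = 0,
    triangle_subset=None,
    level: str = "coarse",
    parent_region: int | None = None,
) -> RegionPartition:
    """Partition a triangle subset into ``n_regions`` contiguous regions.

    Area-weighted k-means on triangle centroids (centroidal relaxation)
    followed by connectivity repair: any triangle stranded outside its
    region's main connected component is reassigned to the adjacent
    region with the largest shared boundary.  Deterministic for a fixed
    seed.
    """
    if triangle_subset is None:
        triangle_ids = np.arange(mesh.n_triangles, dtype=np.int64)
    else:
        triangle_ids = np.asarray(triangle_subset, dtype=np.int64)
    n_tris = len(triangle_ids)
    if n_regions < 1 or n_regions > n_tris:
        raise ValueError(
            f"n_regions must be in [1, {n_tris}] for this subset, got {n_regions}"
        )

    areas = mesh.triangle_areas[triangle_ids]
    if n_regions == 1:
        labels = np.zeros(n_tris, dtype=np.int64)
        return RegionPartition(
            level=level,
            triangle_ids=triangle_ids,
            labels=labels,
            region_areas=np.array([areas.sum()]),
            parent_region=parent_region,
        )

    centroids = mesh.triangle_centroids[triangle_ids]
    labels = _weighted_kmeans(centroids, areas, n_regions, seed)
    labels = _repair_contiguity(mesh, triangle_ids, labels, n_regions)

    region_areas = np.bincount(labels, weights=areas, minlength=n_regions)
    if np.any(region_areas <= 0):
        raise RuntimeError("partition produced an empty region")
    return RegionPartition(
        level=level,
        triangle_ids=triangle_ids,
        labels=labels,
        region_areas=region_areas,
        parent_region=parent_region,
    )


def _weighted_kmeans(points, weights, k, seed):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=3, random_state=int(seed) % (2**31))
    return km.fit_predict(points, sample_weight=weights).astype(np.int64)


def _subset_adjacency(mesh: SurfaceMesh, triangle_ids: np.ndarray):
    """Pairs (i, j) of local subset indices of edge-adjacent triangles."""
    pos = np.full(mesh.n_triangles, -1, dtype=np.int64)
    pos[triangle_ids] = np.arange(len(triangle_ids))
    fa = mesh.face_adjacency
    a, b = pos[fa[:, 0]], pos[fa[:, 1]]
    keep = (a >= 0) & (b >= 0)
    return a[keep], b[keep]


def _repair_contiguity(mesh, triangle_ids, labels, n_regions, max_rounds: int = 50):
    a, b = _subset_adjacency(mesh, triangle_ids)
    n = len(triangle_ids)
    for _ in range(max_rounds):
        same = labels[a] == labels[b]
        graph = coo_matrix(
            (np.ones(same.sum()), (a[same], b[same])), shape=(n, n)
        )
        n_comp, comp = connected_components(graph, directed=False)
        # find, per region, its largest component (by triangle count)
        stranded = np.zeros(n, dtype=bool)
        for r in range(n_regions):
            in_r = labels == r
            comps, counts = np.unique(comp[in_r], return_counts=True)
            if len(comps) <= 1:
                continue
            main = comps[np.argmax(counts)]
            stranded |= in_r & (comp != main)
        if not stranded.any():
            break
        # reassign stranded triangles to the neighboring region with the
        # largest shared boundary (edge count); triangles with no
        # non-stranded neighbor wait for the next round
        new_labels = labels.copy()
        for i in np.flatnonzero(stranded):
            nbr = np.concatenate([b[a == i], a[b == i]])
            nbr = nbr[~stranded[nbr]]
            if len(nbr) == 0:
                continue
            cand, counts = np.unique(labels[nbr], return_counts=True)
            new_labels[i] = cand[np.argmax(counts)]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def region_centroids_on_surface(
    mesh: SurfaceMesh, partition: RegionPartition
) -> np.ndarray:
    """Area-weighted centroid of each region, projected to the surface."""
    cent = mesh.triangle_centroids[partition.triangle_ids]
    areas = mesh.triangle_areas[partition.triangle_ids]
    out = np.zeros((partition.region_count, 3))
    for r in range(partition.region_count):
        m = partition.labels == r
        out[r] = np.average(cent[m], axis=0, weights=areas[m])
    return mesh.project_points(out)


def assign_regions_to_territories(
    mesh: SurfaceMesh, partition: RegionPartition, seeds: ArterialSeedSet
) -> np.ndarray:
    """Territory label per coarse region: the nearest territory seed
    (Euclidean distance from the region's surface centroid)."""
    cent = region_centroids_on_surface(mesh, partition)
    seed_pos = np.array([seeds.seed_by_territory(t).position for t in TERRITORIES])
    d = np.linalg.norm(cent[:, None, :] - seed_pos[None, :, :], axis=2)
    return np.array(TERRITORIES, dtype=object)[np.argmin(d, axis=1)]


# ----------------------------------------------------------------------
# CCO-style growth


def _point_segment_distance(p, a, b):
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1), t


class _GrowingTree:
    """Incremental binary tree over explicit node positions.

    Tracks parent pointers and per-edge downstream flow so that the
    connection cost of a new terminal can weight length by flow.
    """

    def __init__(self, root_pos):
        self.pos = [np.asarray(root_pos, dtype=float)]
        self.parent = [-1]  # local node index -> parent local index
        self.flow = [0.0]  # flow of edge (parent -> node); root unused
        self.is_terminal = [False]
        self.terminal_payload = [None]

    def _propagate(self, node, dq):
        while node > 0:
            self.flow[node] += dq
            node = self.parent[node]

    def add_terminal(self, t_pos, q, payload, k_candidates):
        t_pos = np.asarray(t_pos, dtype=float)
        n = len(self.pos)
        if n == 1:
            self.pos.append(t_pos)
            self.parent.append(0)
            self.flow.append(q)
            self.is_terminal.append(True)
            self.terminal_payload.append(payload)
            return
        # candidate segments: all edges (parent[i] -> i), i >= 1
        nodes = np.arange(1, n)
        a = np.array([self.pos[self.parent[i]] for i in nodes])
        b = np.array([self.pos[i] for i in nodes])
        dist, t_par = _point_segment_distance(t_pos[None].repeat(len(nodes), 0), a, b)
        k = min(k_candidates, len(nodes))
        order = np.argsort(dist, kind="stable")[:k]
        best = None
        for idx in order:
            child = nodes[idx]
            # bifurcation point on the segment, kept off the endpoints so
            # the split never degenerates
            s = float(np.clip(t_par[idx], 0.15, 0.85))
            x = a[idx] + s * (b[idx] - a[idx])
            q_seg = self.flow[child]
            extra = np.linalg.norm(x - a[idx]) + np.linalg.norm(b[idx] - x) - np.linalg.norm(
                b[idx] - a[idx]
            )
            cost = q * np.linalg.norm(x - t_pos) + q_seg * extra
            if best is None or cost < best[0]:
                best = (cost, child, x)
        _, child, x = best
        par = self.parent[child]
        # split (par -> child) at x and hang the terminal off x
        xi = len(self.pos)
        self.pos.append(x)
        self.parent.append(par)
        self.flow.append(self.flow[child])
        self.is_terminal.append(False)
        self.terminal_payload.append(None)
        self.parent[child] = xi
        ti = len(self.pos)
        self.pos.append(t_pos)
        self.parent.append(xi)
        self.flow.append(q)
        self.is_terminal.append(True)
        self.terminal_payload.append(payload)
        self._propagate(xi, q)


def _grow_tree_into_network(
    net: VascularNetwork,
    root_node: int,
    terminal_positions: np.ndarray,
    terminal_flows: np.ndarray,
    terminal_regions: np.ndarray,
    terminal_subregions: np.ndarray,
    territory: str,
    kind: str,
    terminal_role: str,
    params: TreeGrowthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow one tree and append it to ``net``; returns terminal node ids
    aligned with ``terminal_positions``."""
    tree = _GrowingTree(net.positions[root_node])
    order = rng.permutation(len(terminal_positions))
    for i in order:
        tree.add_terminal(
            terminal_positions[i],
            float(terminal_flows[i]),
            int(i),
            params.cco_candidate_connections,
        )
    # map local tree nodes to network nodes
    local_to_net = {0: root_node}
    terminal_ids = np.full(len(terminal_positions), -1, dtype=np.int64)
    for li in range(1, len(tree.pos)):
        if tree.is_terminal[li]:
            payload = tree.terminal_payload[li]
            nid = net.add_nodes(
                tree.pos[li],
                terminal_role,
                territory=territory,
                region=int(terminal_regions[payload]),
                subregion=int(terminal_subregions[payload]),
            )[0]
            terminal_ids[payload] = nid
        else:
            nid = net.add_nodes(tree.pos[li], ROLE_JUNCTION, territory=territory)[0]
        local_to_net[li] = nid
    src, dst, length = [], [], []
    for li in range(1, len(tree.pos)):
        pa = tree.parent[li]
        src.append(local_to_net[pa])
        dst.append(local_to_net[li])
        length.append(
            max(np.linalg.norm(np.asarray(tree.pos[li]) - np.asarray(tree.pos[pa])), 1e-6)
            * 1.0e3
        )
    # placeholder diameters; assign_diameters_murray sets the real ones
    net.add_edges(src, dst, 1.0, length, kind)
    return terminal_ids


def grow_coarse_trees(
    mesh: SurfaceMesh,
    partition: RegionPartition,
    seeds: ArterialSeedSet,
    params: TreeGrowthParams,
    region_territory: np.ndarray | None = None,
) -> VascularNetwork:
    """Build inlets, seeds, feeding stubs and one coarse tree per
    territory, with exactly one terminal per coarse region placed at the
    region's surface centroid.

    Terminal target flow is q_i^c = Q |Omega_i^c| / |Omega|.
    """
    if region_territory is None:
        region_territory = assign_regions_to_territories(mesh, partition, seeds)
    rng = np.random.default_rng(params.seed)
    net = VascularNetwork()

    inlet_ids = {}
    for label, pos in seeds.inlet_positions.items():
        inlet_ids[label] = net.add_nodes(pos, ROLE_INLET, territory=label)[0]
    seed_ids = {}
    for s in seeds.seeds:
        seed_ids[s.territory] = net.add_nodes(
            s.position, ROLE_SEED, territory=s.territory
        )[0]
    for e in seeds.feeding_edges:
        net.add_edges(
            inlet_ids[e.inlet],
            seed_ids[e.territory],
            e.diameter_um,
            e.length_um,
            KIND_STUB,
        )

    total_area = mesh.total_area
    centroids = region_centroids_on_surface(mesh, partition)
    flows = params.total_flow_ml_min * partition.region_areas / total_area

    for territory in TERRITORIES:
        regions = np.flatnonzero(region_territory == territory)
        if len(regions) == 0:
            raise RuntimeError(f"territory {territory} has no assigned coarse region")
        _grow_tree_into_network(
            net,
            seed_ids[territory],
            centroids[regions],
            flows[regions],
            regions,
            np.full(len(regions), -1),
            territory,
            KIND_COARSE,
            ROLE_COARSE_TERMINAL,
            params,
            rng,
        )
    net.validate()
    return net


def grow_fine_trees(
    mesh: SurfaceMesh,
    net: VascularNetwork,
    fine_partitions: dict,
    params: TreeGrowthParams,
) -> VascularNetwork:
    """Grow an independent fine tree from every coarse terminal.

    ``fine_partitions`` maps coarse-region id -> RegionPartition of that
    region's triangles into N2 fine subregions.  Fine terminals carry a
    global subregion id assigned consecutively by (region, local id).
    Growth never leaves the parent coarse region: terminals sit at fine
    subregion centroids, which lie inside the region by construction.
    """
    net = net.copy()
    rng = np.random.default_rng(params.seed + 1)
    total_area = mesh.total_area
    coarse_terminals = net.nodes_with_role(ROLE_COARSE_TERMINAL)
    # deterministic global subregion numbering
    offsets, acc = {}, 0
    for r in sorted(fine_partitions):
        offsets[r] = acc
        acc += fine_partitions[r].region_count
    for node in coarse_terminals:
        region = int(net.node_region[node])
        if region not in fine_partitions:
            raise KeyError(f"missing fine partition for coarse region {region}")
        part = fine_partitions[region]
        cent = region_centroids_on_surface(mesh, part)
        flows = params.total_flow_ml_min * part.region_areas / total_area
        sub_ids = offsets[region] + np.arange(part.region_count)
        _grow_tree_into_network(
            net,
            int(node),
            cent,
            flows,
            np.full(part.region_count, region),
            sub_ids,
            str(net.node_territory[node]),
            KIND_FINE,
            ROLE_FINE_TERMINAL,
            params,
            rng,
        )
    net.validate()
    return net


# ----------------------------------------------------------------------
# Murray diameter assignment


def assign_diameters_murray(
    net: VascularNetwork,
    params: TreeGrowthParams,
    terminal_flow_overrides: dict | None = None,
) -> VascularNetwork:
    """Assign tree diameters top-down by Murray's law.

    At every bifurcation d_child = d_parent (q_child / q_parent)^(1/gamma),
    which satisfies d_parent^gamma = sum d_child^gamma exactly; the split
    is weighted by subtree terminal-flow shares.  Subtree flows default
    to unit weight per terminal unless ``terminal_flow_overrides`` maps
    terminal node id -> flow.  Diameters are floor-clamped and therefore
    monotone non-increasing from root to terminal.
    """
    net = net.copy()
    gamma = params.murray_exponent
    floor = params.terminal_diameter_floor_um

    tree_edges = np.flatnonzero(
        (net.edge_kind == KIND_COARSE) | (net.edge_kind == KIND_FINE)
    )
    stub_edges = net.edges_with_kind(KIND_STUB)
    if np.any(net.edge_diameter_um[stub_edges] <= floor):
        raise ValueError("root (stub) diameter must exceed the terminal floor")

    # children adjacency over tree edges, rooted at seed nodes
    children = {}
    for e in tree_edges:
        children.setdefault(int(net.edge_source[e]), []).append(int(e))

    # subtree flows by post-order accumulation
    flow_of_edge = {}

    def subtree_flow(edge):
        if edge in flow_of_edge:
            return flow_of_edge[edge]
        tgt = int(net.edge_target[edge])
        kids = children.get(tgt, [])
        if not kids:
            q = 1.0
            if terminal_flow_overrides:
                q = float(terminal_flow_overrides.get(tgt, 1.0))
        else:
            q = sum(subtree_flow(k) for k in kids)
        flow_of_edge[edge] = q
        return q

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, net.n_edges + 100))
    try:
        roots = []
        for seed_node in net.nodes_with_role(ROLE_SEED):
            for e in children.get(int(seed_node), []):
                roots.append((e, None))
        for e, _ in roots:
            subtree_flow(e)
        # top-down diameter propagation (iterative DFS)
        seed_root_diam = {}
        for e in stub_edges:
            tgt = int(net.edge_target[e])
            seed_root_diam[tgt] = float(net.edge_diameter_um[e])
        stack = []
        for seed_node in net.nodes_with_role(ROLE_SEED):
            for e in children.get(int(seed_node), []):
                stack.append((e, seed_root_diam[int(seed_node)]))
        diam = net.edge_diameter_um.copy()
        while stack:
            e, d_parent = stack.pop()
            tgt = int(net.edge_target[e])
            kids = children.get(tgt, [])
            src = int(net.edge_source[e])
            siblings = children.get(src, [])
            if len(siblings) == 1:
                d = d_parent  # pass-through node
            else:
                q_parent = sum(flow_of_edge[s] for s in siblings)
                d = d_parent * (flow_of_edge[e] / q_parent) ** (1.0 / gamma)
            d = max(d, floor)
            diam[e] = d
            for k in kids:
                stack.append((k, d))
    finally:
        sys.setrecursionlimit(old_limit)
    net.edge_diameter_um = diam
    return net


# ----------------------------------------------------------------------
# edge subdivision and surface projection


def subdivide_and_project_edges(
    net: VascularNetwork, mesh: SurfaceMesh, n_sub: int = 10
) -> VascularNetwork:
    """Replace each straight tree edge by a path of ``n_sub`` sub-edges
    through ``n_sub + 1`` nodes whose interior points are projected to
    the nearest point of the cortical surface.

    Endpoints keep their positions, so the projected path length is
    always >= the original chord length; diameters are inherited.
    """
    net = net.copy()
    tree_mask = (net.edge_kind == KIND_COARSE) | (net.edge_kind == KIND_FINE)
    tree_edges = np.flatnonzero(tree_mask)
    if len(tree_edges) == 0:
        return net

    s = net.edge_source[tree_edges]
    t = net.edge_target[tree_edges]
    p0 = net.positions[s]
    p1 = net.positions[t]
    ts = np.arange(1, n_sub) / n_sub  # interior parameters
    interior = p0[:, None, :] + ts[None, :, None] * (p1 - p0)[:, None, :]
    flat = interior.reshape(-1, 3)
    projected = mesh.project_points(flat).reshape(len(tree_edges), n_sub - 1, 3)

    keep = ~tree_mask
    kept = VascularNetwork()
    kept.positions = net.positions
    kept.node_role = net.node_role
    kept.node_territory = net.node_territory
    kept.node_region = net.node_region
    kept.node_subregion = net.node_subregion
    for name in (
        "edge_source",
        "edge_target",
        "edge_diameter_um",
        "edge_length_um",
        "edge_kind",
        "edge_tier",
    ):
        setattr(kept, name, getattr(net, name)[keep])

    # append interior nodes in one batch, then the sub-edges
    n_edges = len(tree_edges)
    territory = net.node_territory[t]
    new_ids = kept.add_nodes(
        projected.reshape(-1, 3),
        ROLE_JUNCTION,
        territory=np.repeat(territory, n_sub - 1),
    ).reshape(n_edges, n_sub - 1)

    chain = np.concatenate(
        [s[:, None], new_ids, t[:, None]], axis=1
    )  # (E, n_sub + 1)
    seg_src = chain[:, :-1].ravel()
    seg_dst = chain[:, 1:].ravel()
    all_pos = kept.positions
    seg_len = (
        np.linalg.norm(all_pos[seg_dst] - all_pos[seg_src], axis=1) * 1.0e3
    )
    seg_len = np.maximum(seg_len, 1.0)  # um floor for degenerate segments
    diam = np.repeat(net.edge_diameter_um[tree_edges], n_sub)
    kinds = np.repeat(net.edge_kind[tree_edges], n_sub)
    for kind in (KIND_COARSE, KIND_FINE):
        m = kinds == kind
        if m.any():
            kept.add_edges(seg_src[m], seg_dst[m], diam[m], seg_len[m], kind)
    kept.validate()
    return kept


def murray_root_diameters(
    territory_area_shares: dict, reference_diameters_um: dict
) -> dict:
    """Murray-consistent root diameters from territory area (= flow)
    shares.

    The six roots share the total cube d^3 of the reference diameter
    set in proportion to each territory's flow share, so that root
    hydraulics obey the same minimum-energy law as the trees they feed.
    Boundary terminal pressures then balance across territories, which
    is what keeps intermediate anastomoses flow-neutral in the normal
    state.
    """
    total_cube = sum(d**3 for d in reference_diameters_um.values())
    return {
        t: (total_cube * share) ** (1.0 / 3.0)
        for t, share in territory_area_shares.items()
    }


def find_rmca_trunk_edge(net: VascularNetwork) -> int:
    """Edge id of the R-ICA -> RMCA feeding stub (the occlusion target)."""
    stubs = net.edges_with_kind(KIND_STUB)
    for e in stubs:
        tgt = int(net.edge_target[e])
        if (
            net.node_role[tgt] == ROLE_SEED
            and net.node_territory[tgt] == "RMCA"
        ):
            return int(e)
    raise LookupError("network has no RMCA trunk stub edge")
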