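"""Vascular network container.

A :class:`VascularNetwork` is a plain node/edge graph held in flat numpy
arrays: node positions (mm) with a role, territory, coarse-region and
fine-subregion label per node, and edges carrying a diameter (um), a
length (um), a structural kind and an anastomosis tier tag.

Array storage (rather than a per-node object graph) keeps whole-brain
scale networks (10^5--10^6 edges) cheap to assemble, copy and hand to the
sparse flow solver; :meth:`VascularNetwork.to_networkx` bridges to
networkx when graph algorithms or GraphML serialization are needed.
"""

from __future__ import annotations

import numpy as np

#: node roles
ROLE_INLET = "inlet"
ROLE_SEED = "seed"
ROLE_JUNCTION = "junction"
ROLE_COARSE_TERMINAL = "coarse_terminal"
ROLE_FINE_TERMINAL = "fine_terminal"
ROLE_PIAL = "pial"
ROLE_PENETRATING_TERMINAL = "penetrating_terminal"

#: edge kinds and their anastomosis tier tags.  Tier 1 is the circle-of-
#: Willis level (inlet stubs), tier 2 the intermediate anastomoses, tier 3
#: the pial network; tree edges, penetrating arterioles and terminal
#: connectors carry tier 0 (not an anastomosis).
KIND_STUB = "stub"
KIND_COARSE = "coarse"
KIND_FINE = "fine"
KIND_ANASTOMOSIS = "anastomosis"
KIND_PIAL = "pial"
KIND_PENETRATING = "penetrating"
KIND_CONNECTOR = "connector"

TIER_OF_KIND = {
    KIND_STUB: 1,
    KIND_COARSE: 0,
    KIND_FINE: 0,
    KIND_ANASTOMOSIS: 2,
    KIND_PIAL: 3,
    KIND_PENETRATING: 0,
    KIND_CONNECTOR: 0,
}


class VascularNetwork:
    """Node/edge graph of an arterial network.

    Attributes
    ----------
    positions : (N, 3) float array, node coordinates in mm.
    node_role : (N,) str array, one of the ``ROLE_*`` constants.
    node_territory : (N,) str array, main-artery territory label or "".
    node_region : (N,) int array, coarse-region id or -1.
    node_subregion : (N,) int array, global fine-subregion id or -1.
    edge_source, edge_target : (E,) int arrays of node ids.
    edge_diameter_um, edge_length_um : (E,) float arrays.
    edge_kind : (E,) str array of ``KIND_*`` constants.
    edge_tier : (E,) int array, derived from the kind.
    """

    def __init__(self):
        self.positions = np.empty((0, 3), dtype=float)
        self.node_role = np.empty(0, dtype=object)
        self.node_territory = np.empty(0, dtype=object)
        self.node_region = np.empty(0, dtype=np.int64)
        self.node_subregion = np.empty(0, dtype=np.int64)
        self.edge_source = np.empty(0, dtype=np.int64)
        self.edge_target = np.empty(0, dtype=np.int64)
        self.edge_diameter_um = np.empty(0, dtype=float)
        self.edge_length_um = np.empty(0, dtype=float)
        self.edge_kind = np.empty(0, dtype=object)
        self.edge_tier = np.empty(0, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edge_source)

    def add_nodes(
        self,
        positions,
        role: str,
        territory=None,
        region=None,
        subregion=None,
    ) -> np.ndarray:
        """Append nodes and return their new ids."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        start = self.n_nodes
        self.positions = np.vstack([self.positions, positions])
        self.node_role = np.concatenate([self.node_role, np.full(n, role, dtype=object)])

        def _field(values, default, dtype):
            if values is None:
                arr = np.full(n, default, dtype=dtype)
            else:
                arr = np.asarray(values, dtype=dtype)
                if arr.ndim == 0:
                    arr = np.full(n, arr[()], dtype=dtype)
            return arr

        self.node_territory = np.concatenate(
            [self.node_territory, _field(territory, "", object)]
        )
        self.node_region = np.concatenate(
            [self.node_region, _field(region, -1, np.int64)]
        )
        self.node_subregion = np.concatenate(
            [self.node_subregion, _field(subregion, -1, np.int64)]
        )
        return np.arange(start, start + n, dtype=np.int64)

    def add_edges(self, source, target, diameter_um, length_um, kind: str) -> np.ndarray:
        """Append edges of one kind and return their new ids."""
        source = np.atleast_1d(np.asarray(source, dtype=np.int64))
        target = np.atleast_1d(np.asarray(target, dtype=np.int64))
        n = len(source)
        diameter_um = np.broadcast_to(np.asarray(diameter_um, dtype=float), (n,))
        length_um = np.broadcast_to(np.asarray(length_um, dtype=float), (n,))
        if np.any(diameter_um <= 0) or np.any(length_um <= 0):
            raise ValueError("edge diameters and lengths must be positive")
        if kind not in TIER_OF_KIND:
            raise ValueError(f"unknown edge kind {kind!r}")
        start = self.n_edges
        self.edge_source = np.concatenate([self.edge_source, source])
        self.edge_target = np.concatenate([self.edge_target, target])
        self.edge_diameter_um = np.concatenate([self.edge_diameter_um, np.asarray(diameter_um)])
        self.edge_length_um = np.concatenate([self.edge_length_um, np.asarray(length_um)])
        self.edge_kind = np.concatenate([self.edge_kind, np.full(n, kind, dtype=object)])
        self.edge_tier = np.concatenate(
            [self.edge_tier, np.full(n, TIER_OF_KIND[kind], dtype=np.int64)]
        )
        return np.arange(start, start + n, dtype=np.int64)

    # ------------------------------------------------------------------
    def copy(self) -> "VascularNetwork":
        new = VascularNetwork()
        for name in (
            "positions",
            "node_role",
            "node_territory",
            "node_region",
            "node_subregion",
            "edge_source",
            "edge_target",
            "edge_diameter_um",
            "edge_length_um",
            "edge_kind",
            "edge_tier",
        ):
            setattr(new, name, getattr(self, name).copy())
        return new

    def nodes_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.node_role == role)

    def edges_with_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.edge_kind == kind)

    def edge_lengths_from_positions(self, edge_ids=None) -> np.ndarray:
        """Euclidean source->target distances in um (positions are mm)."""
        if edge_ids is None:
            s, t = self.edge_source, self.edge_target
        else:
            s, t = self.edge_source[edge_ids], self.edge_target[edge_ids]
        d = self.positions[t] - self.positions[s]
        return np.linalg.norm(d, axis=1) * 1.0e3

    def validate(self) -> None:
        """Check index ranges and positivity; raise ValueError on defects."""
        if self.n_edges:
            lo = min(self.edge_source.min(), self.edge_target.min())
            hi = max(self.edge_source.max(), self.edge_target.max())
            if lo < 0 or hi >= self.n_nodes:
                raise ValueError("edge endpoint out of node range")
        if np.any(self.edge_diameter_um <= 0):
            raise ValueError("non-positive edge diameter")
        if np.any(self.edge_length_um <= 0):
            raise ValueError("non-positive edge length")

    # ------------------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(
                int(i),
                x=float(self.positions[i, 0]),
                y=float(self.positions[i, 1]),
                z=float(self.positions[i, 2]),
                role=str(self.node_role[i]),
                territory=str(self.node_territory[i]),
                region=int(self.node_region[i]),
                subregion=int(self.node_subregion[i]),
            )
        for e in range(self.n_edges):
            g.add_edge(
                int(self.edge_source[e]),
                int(self.edge_target[e]),
                edge_id=int(e),
                source=int(self.edge_source[e]),
                target=int(self.edge_target[e]),
                diameter_um=float(self.edge_diameter_um[e]),
                length_um=float(self.edge_length_um[e]),
                kind=str(self.edge_kind[e]),
                tier=int(self.edge_tier[e]),
            )
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"VascularNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
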