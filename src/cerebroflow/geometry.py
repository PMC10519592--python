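"""Cortical surface meshes and inlet-artery seeds.

The simulator operates on a closed triangulated surface standing in for
the cerebral cortex.  Real imaged geometry can be loaded from standard
mesh formats (PLY/STL/OFF); for reproducible studies a synthetic cortex
— a smooth or wrinkled ellipsoid — is generated here.  The large
arteries normally extracted from angiographic images are replaced by a
canonical set of six territory seed points (left/right anterior, middle
and posterior cerebral arteries) fed by four inlets (internal carotid
and vertebral arteries), with one feeding stub flagged as the RMCA trunk
so occlusion experiments have a well-defined target.

Units: coordinates in mm, areas in mm^2, diameters in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import trimesh
from scipy.spatial import cKDTree

TERRITORIES = ("LACA", "RACA", "LMCA", "RMCA", "LPCA", "RPCA")
INLETS = ("L-ICA", "R-ICA", "L-VA", "R-VA")

#: which inlet feeds which territory in the canonical layout: carotids
#: feed the anterior and middle territories, vertebrals the posterior.
CANONICAL_FEEDING = {
    "LACA": "L-ICA",
    "LMCA": "L-ICA",
    "RACA": "R-ICA",
    "RMCA": "R-ICA",
    "LPCA": "L-VA",
    "RPCA": "R-VA",
}

#: default root diameters (um); modeling inputs, configurable.
DEFAULT_ROOT_DIAMETERS = {
    "LACA": 2000.0,
    "RACA": 2000.0,
    "LMCA": 2500.0,
    "RMCA": 2500.0,
    "LPCA": 2000.0,
    "RPCA": 2000.0,
}

#: unit directions of the canonical seed sextants (x: left-/right+,
#: y: posterior-/anterior+, z: inferior-/superior+).
_SEXTANT_DIRECTIONS = {
    "LACA": (-0.35, 0.90, 0.25),
    "RACA": (0.35, 0.90, 0.25),
    "LMCA": (-1.00, 0.00, 0.10),
    "RMCA": (1.00, 0.00, 0.10),
    "LPCA": (-0.35, -0.90, 0.25),
    "RPCA": (0.35, -0.90, 0.25),
}


class MeshValidationError(ValueError):
    """Raised when a surface fails the closed-manifold requirements."""


@dataclass
class SurfaceMesh:
    """Closed triangulated surface with per-triangle areas.

    ``vertices`` are (V, 3) mm coordinates, ``triangles`` (T, 3) vertex
    index triples with consistent outward winding.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(
            self.vertices
        ):
            raise MeshValidationError("triangle references vertex out of range")

    # -- derived quantities -------------------------------------------
    @cached_property
    def _trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def total_area(self) -> float:
        """Total surface area |Omega| in mm^2."""
        return float(self.triangle_areas.sum())

    @cached_property
    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @cached_property
    def face_adjacency(self) -> np.ndarray:
        """(M, 2) pairs of triangle indices sharing an edge."""
        return np.asarray(self._trimesh.face_adjacency, dtype=np.int64)

    @cached_property
    def triangle_mean_edge_lengths(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        e = np.stack(
            [
                np.linalg.norm(v[:, 1] - v[:, 0], axis=1),
                np.linalg.norm(v[:, 2] - v[:, 1], axis=1),
                np.linalg.norm(v[:, 0] - v[:, 2], axis=1),
            ],
            axis=1,
        )
        return e.mean(axis=1)

    @cached_property
    def _centroid_tree(self) -> cKDTree:
        return cKDTree(self.triangle_centroids)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def euler_characteristic(self) -> int:
        return int(self._trimesh.euler_number)

    # -- validation ----------------------------------------------------
    def validate_closed(self) -> None:
        """Require a closed, consistently oriented 2-manifold."""
        tm = self._trimesh
        if not tm.is_watertight:
            raise MeshValidationError("mesh is not watertight (open boundary)")
        if not tm.is_winding_consistent:
            raise MeshValidationError("mesh winding is not consistent")
        if np.any(self.triangle_areas <= 0):
            raise MeshValidationError("mesh contains degenerate (zero-area) triangles")

    # -- geometric queries --------------------------------------------
    def project_points(self, points: np.ndarray, k: int = 12) -> np.ndarray:
        """Closest points on the surface to each query point.

        Candidate triangles come from the ``k`` nearest triangle
        centroids; the exact closest point on each candidate triangle is
        then computed and the nearest retained.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, self.n_triangles)
        _, cand = self._centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        tri = self.vertices[self.triangles[cand]]  # (P, k, 3, 3)
        closest = _closest_point_on_triangles(
            points[:, None, :], tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
        )
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        return closest[np.arange(len(points)), best]


def _closest_point_on_triangles(p, a, b, c):
    """Vectorized closest point on triangle (a, b, c) to point p.

    Standard barycentric-region case analysis; all inputs broadcast to a
    common (..., 3) shape.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom
    out = a + v[..., None] * ab + w[..., None] * ac  # interior case

    # edge/vertex regions override the interior formula
    t_ab = np.clip(d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0, 1.0)
    on_ab = a + t_ab[..., None] * ab
    t_ac = np.clip(d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0, 1.0)
    on_ac = a + t_ac[..., None] * ac
    t_bc = np.clip(
        (d4 - d3) / np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) + (d5 - d6), 1.0),
        0.0,
        1.0,
    )
    on_bc = b + t_bc[..., None] * (c - b)

    def _pick(cond, val, cur):
        return np.where(cond[..., None], val, cur)

    out = _pick((vc <= 0) & (d1 >= 0) & (d3 <= 0), on_ab, out)
    out = _pick((vb <= 0) & (d2 >= 0) & (d6 <= 0), on_ac, out)
    out = _pick((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0), on_bc, out)
    out = _pick((d1 <= 0) & (d2 <= 0), np.broadcast_to(a, out.shape), out)
    out = _pick((d3 >= 0) & (d4 <= d3), np.broadcast_to(b, out.shape), out)
    out = _pick((d6 >= 0) & (d5 <= d6), np.broadcast_to(c, out.shape), out)
    return out


# ----------------------------------------------------------------------
# synthetic cortex generation


def _unit_sphere_mesh(target_triangle_count: int) -> trimesh.Trimesh:
    """Unit sphere whose triangle count is as close as possible to target.

    Icosphere refinements (20 * 4^n triangles, near-uniform degree-6
    vertices) are preferred; when no refinement level lands within 15% of
    the target a UV sphere with a tuned subdivision count is used.
    """
    ico_counts = [20 * 4**n for n in range(9)]
    best_n = int(np.argmin([abs(c - target_triangle_count) for c in ico_counts]))
    if abs(ico_counts[best_n] - target_triangle_count) <= 0.15 * target_triangle_count:
        return trimesh.creation.icosphere(subdivisions=best_n, radius=1.0)
    # UV sphere: search square subdivision counts for the closest face count
    best = None
    s0 = max(4, int(np.sqrt(target_triangle_count / 2.0)))
    for s in range(max(4, s0 - 8), s0 + 9):
        m = trimesh.creation.uv_sphere(radius=1.0, count=(s, s))
        err = abs(len(m.faces) - target_triangle_count)
        if best is None or err < best[0]:
            best = (err, m)
    return best[1]


def generate_synthetic_cortex(
    target_triangle_count: int,
    semi_axes=(60.0, 60.0, 60.0),
    wrinkle_amplitude: float = 0.0,
    wrinkle_frequency: int = 6,
    seed: int = 0,
) -> SurfaceMesh:
    """Generate a closed synthetic cortical surface.

    An ellipsoid with the given semi-axes (mm) is triangulated with
    roughly ``target_triangle_count`` triangles; an optional smooth
    radial wrinkle field (amplitude in mm, integer angular frequency,
    random phases from ``seed``) adds folding-like relief.  The result is
    always a closed, consistently oriented genus-0 surface.
    """
    if target_triangle_count < 20:
        raise ValueError("target_triangle_count must be at least 20")
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be three positive lengths (mm)")
    if wrinkle_amplitude < 0:
        raise ValueError("wrinkle_amplitude must be non-negative")

    base = _unit_sphere_mesh(target_triangle_count)
    unit = np.asarray(base.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    verts = unit * semi_axes

    if wrinkle_amplitude > 0:
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
        f = int(round(wrinkle_frequency))
        theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
        phi = np.arctan2(unit[:, 1], unit[:, 0])
        # integer azimuthal frequency keeps the field continuous across
        # the atan2 seam
        bump = np.sin(f * theta + phases[0]) * np.cos(f * phi + phases[1])
        verts = verts * (1.0 + wrinkle_amplitude * bump / np.linalg.norm(verts, axis=1))[
            :, None
        ]

    mesh = SurfaceMesh(vertices=verts, triangles=np.asarray(base.faces))
    mesh.validate_closed()
    return mesh


# ----------------------------------------------------------------------
# inlet-artery seeds


@dataclass
class ArterialSeed:
    territory: str
    position: np.ndarray  # (3,) mm, on/near the surface
    root_diameter_um: float
    inlet: str


@dataclass
class FeedingEdge:
    inlet: str
    territory: str
    diameter_um: float
    length_um: float
    is_rmca_trunk: bool = False


@dataclass
class ArterialSeedSet:
    """Six territory seeds plus inlet stubs replacing the imaged large
    arteries (circle of Willis level)."""

    seeds: list  # of ArterialSeed, in TERRITORIES order
    inlet_positions: dict  # inlet label -> (3,) mm
    feeding_edges: list = field(default_factory=list)  # of FeedingEdge

    def __post_init__(self):
        labels = [s.territory for s in self.seeds]
        if sorted(labels) != sorted(TERRITORIES):
            raise ValueError("seed set must contain each of the six territories once")
        for s in self.seeds:
            if s.root_diameter_um <= 0:
                raise ValueError("root diameters must be positive")
        for e in self.feeding_edges:
            if e.diameter_um <= 0 or e.length_um <= 0:
                raise ValueError("feeding edge diameters and lengths must be positive")
        fed = {e.territory for e in self.feeding_edges}
        if fed != set(TERRITORIES):
            raise ValueError("every seed must be reachable from an inlet stub")

    def seed_by_territory(self, territory: str) -> ArterialSeed:
        for s in self.seeds:
            if s.territory == territory:
                return s
        raise KeyError(territory)


def generate_seed_arteries(
    mesh: SurfaceMesh,
    root_diameters=None,
    seed: int = 0,
) -> ArterialSeedSet:
    """Place the canonical six territory seeds on a cortical surface.

    Seeds sit at the surface points nearest the six sextant directions
    (left/right x anterior/middle/posterior); the four inlets sit below
    the surface centroid, and each territory gets one feeding stub from
    its canonical inlet.  The R-ICA -> RMCA stub is flagged as the RMCA
    trunk, the target of occlusion experiments.
    """
    root_diameters = dict(DEFAULT_ROOT_DIAMETERS, **(root_diameters or {}))
    center = mesh.vertices.mean(axis=0)
    extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)

    directions = np.array([_SEXTANT_DIRECTIONS[t] for t in TERRITORIES])
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    probe = center + directions * extent / 2.0
    on_surface = mesh.project_points(probe)

    seeds = [
        ArterialSeed(
            territory=t,
            position=on_surface[i],
            root_diameter_um=float(root_diameters[t]),
            inlet=CANONICAL_FEEDING[t],
        )
        for i, t in enumerate(TERRITORIES)
    ]

    inlet_positions = {
        "L-ICA": center + np.array([-0.15, 0.05, -0.65]) * extent,
        "R-ICA": center + np.array([0.15, 0.05, -0.65]) * extent,
        "L-VA": center + np.array([-0.05, -0.25, -0.70]) * extent,
        "R-VA": center + np.array([0.05, -0.25, -0.70]) * extent,
    }

    feeding_edges = []
    for s in seeds:
        length_mm = float(np.linalg.norm(s.position - inlet_positions[s.inlet]))
        feeding_edges.append(
            FeedingEdge(
                inlet=s.inlet,
                territory=s.territory,
                diameter_um=s.root_diameter_um,
                length_um=length_mm * 1.0e3,
                is_rmca_trunk=(s.territory == "RMCA"),
            )
        )
    return ArterialSeedSet(
        seeds=seeds, inlet_positions=inlet_positions, feeding_edges=feeding_edges
    )


# ----------------------------------------------------------------------
# mesh I/O

_FORMATS = {"ply": "ply", "stl": "stl_ascii", "off": "off"}


def save_mesh(mesh: SurfaceMesh, path, file_format: str | None = None) -> None:
    """Write a mesh as ASCII PLY, STL or OFF (chosen from the extension
    when ``file_format`` is omitted)."""
    path = str(path)
    fmt = (file_format or path.rsplit(".", 1)[-1]).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    else:
        data = tm.export(file_type=_FORMATS[fmt])
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_mesh(path, file_format: str | None = None) -> SurfaceMesh:
    """Load and validate a closed surface from PLY/STL/OFF."""
    path = str(path)
    fmt = (file_format or path.rsplit(".", 1)[-1]).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    # STL stores loose triangles, so vertices must be merged to recover
    # topology; indexed formats are loaded verbatim.
    tm = trimesh.load(
        path, file_type="stl" if fmt == "stl" else fmt, process=(fmt == "stl")
    )
    if isinstance(tm, trimesh.Scene):  # pragma: no cover
        tm = tm.to_mesh()
    mesh = SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        triangles=np.asarray(tm.faces, dtype=np.int64),
    )
    mesh.validate_closed()
    return mesh
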