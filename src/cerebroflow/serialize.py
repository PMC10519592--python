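"""Network and solution serialization.

Three interchangeable network formats: GraphML (via networkx), a CSV
pair (nodes.csv / edges.csv) and VTK XML PolyData (.vtp, ASCII) for
visualization in ParaView.  Round-trips preserve topology exactly and
positions/diameters/lengths to full float precision (floats are written
with repr-level precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import VascularNetwork

_NODE_COLUMNS = ["id", "x", "y", "z", "role", "territory", "region", "subregion"]
_EDGE_COLUMNS = ["id", "source", "target", "diameter_um", "length_um", "kind", "tier"]
_FLOAT_FMT = "%.17g"


def network_to_frames(net: VascularNetwork):
    nodes = pd.DataFrame(
        {
            "id": np.arange(net.n_nodes),
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "z": net.positions[:, 2],
            "role": net.node_role,
            "territory": net.node_territory,
            "region": net.node_region,
            "subregion": net.node_subregion,
        }
    )
    edges = pd.DataFrame(
        {
            "id": np.arange(net.n_edges),
            "source": net.edge_source,
            "target": net.edge_target,
            "diameter_um": net.edge_diameter_um,
            "length_um": net.edge_length_um,
            "kind": net.edge_kind,
            "tier": net.edge_tier,
        }
    )
    return nodes, edges


def network_from_frames(nodes: pd.DataFrame, edges: pd.DataFrame) -> VascularNetwork:
    for col in _NODE_COLUMNS:
        if col not in nodes.columns:
            raise ValueError(f"nodes table missing field {col!r}")
    for col in _EDGE_COLUMNS:
        if col not in edges.columns:
            raise ValueError(f"edges table missing field {col!r}")
    nodes = nodes.sort_values("id")
    edges = edges.sort_values("id")
    net = VascularNetwork()
    net.positions = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    net.node_role = nodes["role"].to_numpy(dtype=object)
    net.node_territory = nodes["territory"].fillna("").to_numpy(dtype=object)
    net.node_region = nodes["region"].to_numpy(dtype=np.int64)
    net.node_subregion = nodes["subregion"].to_numpy(dtype=np.int64)
    net.edge_source = edges["source"].to_numpy(dtype=np.int64)
    net.edge_target = edges["target"].to_numpy(dtype=np.int64)
    net.edge_diameter_um = edges["diameter_um"].to_numpy(dtype=float)
    net.edge_length_um = edges["length_um"].to_numpy(dtype=float)
    net.edge_kind = edges["kind"].to_numpy(dtype=object)
    net.edge_tier = edges["tier"].to_numpy(dtype=np.int64)
    net.validate()
    return net


# ----------------------------------------------------------------------
# CSV pair


def save_network_csv(net: VascularNetwork, prefix) -> tuple:
    """Write ``<prefix>.nodes.csv`` and ``<prefix>.edges.csv``."""
    nodes, edges = network_to_frames(net)
    npath, epath = f"{prefix}.nodes.csv", f"{prefix}.edges.csv"
    nodes.to_csv(npath, index=False, float_format=_FLOAT_FMT)
    edges.to_csv(epath, index=False, float_format=_FLOAT_FMT)
    return npath, epath


def load_network_csv(prefix) -> VascularNetwork:
    nodes = pd.read_csv(f"{prefix}.nodes.csv", keep_default_na=False, na_values=[])
    edges = pd.read_csv(f"{prefix}.edges.csv", keep_default_na=False, na_values=[])
    return network_from_frames(nodes, edges)


# ----------------------------------------------------------------------
# GraphML


def save_network_graphml(net: VascularNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def load_network_graphml(path) -> VascularNetwork:
    import networkx as nx

    g = nx.read_graphml(path, node_type=int)
    n = g.number_of_nodes()
    nodes = pd.DataFrame(
        [
            {
                "id": i,
                "x": g.nodes[i]["x"],
                "y": g.nodes[i]["y"],
                "z": g.nodes[i]["z"],
                "role": g.nodes[i]["role"],
                "territory": g.nodes[i].get("territory", ""),
                "region": g.nodes[i].get("region", -1),
                "subregion": g.nodes[i].get("subregion", -1),
            }
            for i in range(n)
        ]
    )
    rows = []
    for u, v, data in g.edges(data=True):
        rows.append(
            {
                "id": data["edge_id"],
                "source": data["source"],
                "target": data["target"],
                "diameter_um": data["diameter_um"],
                "length_um": data["length_um"],
                "kind": data["kind"],
                "tier": data["tier"],
            }
        )
    edges = pd.DataFrame(rows).sort_values("id")
    return network_from_frames(nodes, edges)


# ----------------------------------------------------------------------
# VTK XML PolyData (ASCII)


def save_network_vtp(net: VascularNetwork, path, point_data=None, cell_data=None):
    """Write the network as ASCII VTK XML PolyData: points = nodes,
    lines = edges; optional named float arrays per point/cell."""
    point_data = point_data or {}
    cell_data = cell_data or {}

    def _arr(vals):
        return " ".join(repr(float(v)) for v in np.asarray(vals).ravel())

    lines = []
    lines.append('<?xml version="1.0"?>')
    lines.append(
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">'
    )
    lines.append("  <PolyData>")
    lines.append(
        f'    <Piece NumberOfPoints="{net.n_nodes}" NumberOfVerts="0" '
        f'NumberOfLines="{net.n_edges}" NumberOfStrips="0" NumberOfPolys="0">'
    )
    lines.append("      <Points>")
    lines.append(
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">'
    )
    lines.append("          " + _arr(net.positions))
    lines.append("        </DataArray>")
    lines.append("      </Points>")
    lines.append("      <Lines>")
    conn = np.column_stack([net.edge_source, net.edge_target]).ravel()
    lines.append('        <DataArray type="Int64" Name="connectivity" format="ascii">')
    lines.append("          " + " ".join(str(int(v)) for v in conn))
    lines.append("        </DataArray>")
    lines.append('        <DataArray type="Int64" Name="offsets" format="ascii">')
    lines.append(
        "          " + " ".join(str(2 * (i + 1)) for i in range(net.n_edges))
    )
    lines.append("        </DataArray>")
    lines.append("      </Lines>")
    lines.append("      <PointData>")
    for name, vals in point_data.items():
        lines.append(
            f'        <DataArray type="Float64" Name="{name}" format="ascii">'
        )
        lines.append("          " + _arr(vals))
        lines.append("        </DataArray>")
    lines.append("      </PointData>")
    lines.append("      <CellData>")
    base_cell = {
        "diameter_um": net.edge_diameter_um,
        "length_um": net.edge_length_um,
        "tier": net.edge_tier,
    }
    for name, vals in {**base_cell, **cell_data}.items():
        lines.append(
            f'        <DataArray type="Float64" Name="{name}" format="ascii">'
        )
        lines.append("          " + _arr(vals))
        lines.append("        </DataArray>")
    lines.append("      </CellData>")
    lines.append("    </Piece>")
    lines.append("  </PolyData>")
    lines.append("</VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_network_vtp(path) -> VascularNetwork:
    """Read back the geometry/topology subset written by
    :func:`save_network_vtp` (roles and kinds are not stored in VTP)."""
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    coords = np.fromstring(pts.text.strip(), sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("Lines/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text.strip(), sep=" ", dtype=float).astype(int)
    cell = {}
    for da in piece.findall("CellData/DataArray"):
        cell[da.get("Name")] = np.fromstring(da.text.strip(), sep=" ")
    net = VascularNetwork()
    net.add_nodes(coords, "junction")
    pairs = conn.reshape(-1, 2)
    net.add_edges(
        pairs[:, 0],
        pairs[:, 1],
        cell["diameter_um"],
        cell["length_um"],
        "pial",
    )
    net.edge_tier = cell.get("tier", net.edge_tier).astype(np.int64)
    return net


# ----------------------------------------------------------------------
# dispatch


def save_network(net: VascularNetwork, path, file_format: str | None = None):
    fmt = file_format or _infer_format(path)
    if fmt == "graphml":
        save_network_graphml(net, path)
    elif fmt == "csv":
        save_network_csv(net, _strip_csv_suffix(path))
    elif fmt == "vtp":
        save_network_vtp(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_network(path, file_format: str | None = None) -> VascularNetwork:
    fmt = file_format or _infer_format(path)
    if fmt == "graphml":
        return load_network_graphml(path)
    if fmt == "csv":
        return load_network_csv(_strip_csv_suffix(path))
    if fmt == "vtp":
        return load_network_vtp(path)
    raise ValueError(f"unknown network format {fmt!r}")


def _infer_format(path) -> str:
    p = str(path)
    if p.endswith(".graphml"):
        return "graphml"
    if p.endswith(".vtp"):
        return "vtp"
    return "csv"


def _strip_csv_suffix(path) -> str:
    p = str(path)
    for suffix in (".nodes.csv", ".edges.csv", ".csv"):
        if p.endswith(suffix):
            return p[: -len(suffix)]
    return p


# ----------------------------------------------------------------------
# solutions and reports


def save_solution_csv(net, sol, prefix) -> tuple:
    ppath, fpath = f"{prefix}.pressures.csv", f"{prefix}.flows.csv"
    pd.DataFrame(
        {"node_id": np.arange(net.n_nodes), "pressure_mmHg": sol.pressures_mmhg}
    ).to_csv(ppath, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        {"edge_id": np.arange(net.n_edges), "flow_ml_min": sol.flows_ml_min}
    ).to_csv(fpath, index=False, float_format=_FLOAT_FMT)
    return ppath, fpath


def candidates_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id,
                "terminal_a": c.terminal_a,
                "terminal_b": c.terminal_b,
                "territory_a": c.territory_a,
                "territory_b": c.territory_b,
                "separation_mm": c.separation_mm,
                "diameter_um": c.diameter_um,
                "adopted": c.adopted,
            }
            for c in candidates
        ]
    )


def recovery_report_to_frame(report) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subregion_id": report.subregion_ids,
            "area_mm2": report.subregion_areas_mm2,
            "q_normal": report.q_normal,
            "q_occlusion": report.q_occlusion,
            "ratio": report.ratio,
        }
    )


def greedy_log_to_frame(result) -> pd.DataFrame:
    rows = []
    adopted_at = {c: r for r, c in enumerate(result.adopted_order, start=1)}
    for rnd, cand, rec in result.evaluations:
        rows.append(
            {
                "round": rnd,
                "candidate_id": cand,
                "total_recovery": rec,
                "adopted": adopted_at.get(cand) == rnd,
            }
        )
    return pd.DataFrame(rows)
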