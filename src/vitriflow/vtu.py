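"""Minimal ASCII VTK XML (.vtu/.pvd) output for mesh + field snapshots.

Writes UnstructuredGrid files with triangle cells, point data (temperature,
velocity components, pressure) and cell data (region tag), plus a .pvd
collection indexing the time series.  Plain-text XML, readable by any VTK
tool.
"""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["write_vtu", "write_vtu_series", "read_vtu_points"]

VTK_TRIANGLE = 5


def _fmt(arr, per_line=6):
    flat = np.asarray(arr).ravel()
    lines = []
    for i in range(0, len(flat), per_line):
        lines.append(" ".join(f"{v:.10g}" for v in flat[i:i + per_line]))
    return "\n".join(lines)


def write_vtu(path, mesh, point_data=None, cell_data=None) -> str:
    """Write one mesh snapshot with optional nodal / per-element fields."""
    path = Path(path)
    nodes = np.asarray(mesh.nodes, dtype=float)
    tris = np.asarray(mesh.tris)
    n, m = len(nodes), len(tris)
    pts3 = np.column_stack([nodes, np.zeros(n)])
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if "region" not in cell_data and getattr(mesh, "region", None) is not None:
        cell_data["region"] = mesh.region

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(pts3),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(tris, 12),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(3 * (np.arange(m) + 1), 12),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(np.full(m, VTK_TRIANGLE), 24),
        "        </DataArray>",
        "      </Cells>",
    ]
    if point_data:
        parts.append("      <PointData>")
        for name, arr in point_data.items():
            parts += [f'        <DataArray type="Float64" Name="{escape(name)}" '
                      'format="ascii">', _fmt(arr), "        </DataArray>"]
        parts.append("      </PointData>")
    if cell_data:
        parts.append("      <CellData>")
        for name, arr in cell_data.items():
            parts += [f'        <DataArray type="Float64" Name="{escape(name)}" '
                      'format="ascii">', _fmt(np.asarray(arr, dtype=float)),
                      "        </DataArray>"]
        parts.append("      </CellData>")
    parts += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(parts))
    return str(path)


def write_vtu_series(snapshots, directory, basename="fields") -> str:
    """Write (t, mesh, point_data[, cell_data]) snapshots plus a .pvd index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, snap in enumerate(snapshots):
        t, mesh, point_data = snap[:3]
        cell_data = snap[3] if len(snap) > 3 else None
        name = f"{basename}_{i:04d}.vtu"
        write_vtu(directory / name, mesh, point_data, cell_data)
        entries.append((t, name))
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', "  <Collection>"]
    for t, name in entries:
        lines.append(f'    <DataSet timestep="{t:.10g}" group="" part="0" '
                     f'file="{name}"/>')
    lines += ["  </Collection>", "</VTKFile>", ""]
    pvd = directory / f"{basename}.pvd"
    pvd.write_text("\n".join(lines))
    return str(pvd)


def read_vtu_points(path):
    """Read back points, connectivity and point data from an ASCII .vtu.

    A convenience for round-trip checks; handles only the subset this
    module writes.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = np.fromstring(piece.find("./Points/DataArray").text.replace("\n", " "),
                        sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("./Cells/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text.replace("\n", " "), sep=" ",
                                 dtype=float).astype(int).reshape(-1, 3)
    fields = {}
    pdata = piece.find("./PointData")
    if pdata is not None:
        for da in pdata.findall("./DataArray"):
            fields[da.get("Name")] = np.fromstring(
                da.text.replace("\n", " "), sep=" ")
    return pts[:, :2], conn, fields
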