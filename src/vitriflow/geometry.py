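"""Axisymmetric cuvette geometry, meshing and ALE mesh motion.

The computational domain is a 2D axisymmetric (r, z) cross-section of a
cylindrical container: a CPA column 0 <= r <= R_i, 0 <= z <= fill height,
surrounded by an L-shaped wall (side wall of thickness t_w up to the cuvette
height, and a bottom plate of the same thickness).  z = 0 is the inner
bottom of the container and gravity acts in -z.

The mesh is a structured, conforming triangulation (right triangles on a
tensor grid with alternating diagonals).  The free surface deforms by
moving its nodes with the normal fluid velocity (ALE); interior CPA nodes
follow by Laplacian smoothing and, when element quality degrades past a
threshold, by redistributing nodes along their original radial columns
("incremental remeshing" — connectivity and boundary tags are preserved,
nodal fields are re-interpolated linearly along each column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import tri_geometry, quad_points, QW

__all__ = [
    "AxisymGeometry",
    "AxisymMesh",
    "RemeshRequired",
    "build_mesh",
    "build_box_mesh",
    "mesh_quality",
    "element_quality",
    "move_free_surface",
    "redistribute_columns",
    "surface_normals",
    "cpa_volume",
]

CPA, WALL = 0, 1
REGION_NAMES = {CPA: "cpa", WALL: "wall"}


class RemeshRequired(RuntimeError):
    """Mesh motion produced inverted or unacceptably distorted elements."""


@dataclass(frozen=True)
class AxisymGeometry:
    """Container dimensions in metres.

    Defaults model a cuvette of 12.5 mm external width (treated as the outer
    diameter of the equivalent cylinder), 1.25 mm wall thickness, 45 mm
    height, filled with CPA to 27.5 mm.
    """

    inner_radius: float = 5.0e-3
    wall_thickness: float = 1.25e-3
    height: float = 45.0e-3
    fill_height: float = 27.5e-3

    def __post_init__(self):
        if self.wall_thickness <= 0 or self.inner_radius <= 0:
            raise ValueError("radius and wall thickness must be positive")
        if not 0.0 < self.fill_height < self.height:
            raise ValueError("fill height must lie in (0, height)")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness


@dataclass
class AxisymMesh:
    """Triangulation with region and boundary tags.

    ``edges`` maps a tag name to an (E, 2) array of node pairs.  Interface
    tags (``wall_cpa_interface``, ``cpa_bottom_interface``) are interior
    edges shared by the two regions, kept for boundary-condition purposes.
    ``structure`` carries the column bookkeeping used by redistribution.
    """

    nodes: np.ndarray                 # (N, 2) float, (r, z) in m
    tris: np.ndarray                  # (M, 3) int, CCW
    region: np.ndarray                # (M,) int, CPA=0 / WALL=1
    edges: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    def copy(self) -> "AxisymMesh":
        return AxisymMesh(self.nodes.copy(), self.tris, self.region,
                          self.edges, self.structure)

    def nodes_of(self, tag: str) -> np.ndarray:
        return np.unique(self.edges[tag])

    @property
    def free_surface_nodes(self) -> np.ndarray:
        """Free-surface node ids ordered from the axis to the wall contact."""
        return self.structure["surface_nodes"]

    @property
    def cpa_tris(self) -> np.ndarray:
        return self.tris[self.region == CPA]

    def element_areas(self) -> np.ndarray:
        area, _ = tri_geometry(self.nodes, self.tris)
        return area


def _grid_lines(length, n):
    return np.linspace(0.0, length, n + 1)


def build_mesh(geometry: AxisymGeometry, target_element_count: int = 4000) -> AxisymMesh:
    """Structured conforming triangulation of the CPA + wall cross-section."""
    if target_element_count < 100:
        raise ValueError("target_element_count must be at least 100")
    ri, wt = geometry.inner_radius, geometry.wall_thickness
    hgt, fill = geometry.height, geometry.fill_height

    area_total = ri * fill + wt * (hgt + wt) + ri * wt
    h = np.sqrt(area_total / (target_element_count / 2.0))
    nrc = max(4, round(ri / h))
    nwc = max(2, round(wt / h))
    nzc = max(8, round(fill / h))
    nbz = max(2, round(wt / h))
    ntz = max(2, round((hgt - fill) / h))

    r_lines = np.concatenate([_grid_lines(ri, nrc),
                              ri + _grid_lines(wt, nwc)[1:]])
    z_lines = np.concatenate([-wt + _grid_lines(wt, nbz)[:-1],
                              _grid_lines(fill, nzc),
                              fill + _grid_lines(hgt - fill, ntz)[1:]])
    nr, nz = len(r_lines), len(z_lines)
    i_ri = nrc                      # column index of r = R_i
    j_bot = nbz                     # row index of z = 0
    j_fill = nbz + nzc              # row index of z = fill

    tol = 1e-12
    exists = np.ones((nr, nz), dtype=bool)
    for i in range(nr):
        for j in range(nz):
            if r_lines[i] < ri - tol and z_lines[j] > fill + tol:
                exists[i, j] = False   # air above the CPA column
    node_id = -np.ones((nr, nz), dtype=np.int64)
    coords = []
    for i in range(nr):
        for j in range(nz):
            if exists[i, j]:
                node_id[i, j] = len(coords)
                coords.append((r_lines[i], z_lines[j]))
    nodes = np.array(coords)
    nodes[np.abs(nodes[:, 0]) < tol, 0] = 0.0   # axis nodes exactly at r = 0

    tris, region = [], []
    for i in range(nr - 1):
        for j in range(nz - 1):
            ids = (node_id[i, j], node_id[i + 1, j],
                   node_id[i + 1, j + 1], node_id[i, j + 1])
            if min(ids) < 0:
                continue
            in_cpa = (i + 1 <= i_ri) and (j >= j_bot) and (j + 1 <= j_fill)
            reg = CPA if in_cpa else WALL
            n00, n10, n11, n01 = ids
            if (i + j) % 2 == 0:
                cells = [(n00, n10, n11), (n00, n11, n01)]
            else:
                cells = [(n00, n10, n01), (n10, n11, n01)]
            tris.extend(cells)
            region.extend([reg, reg])
    tris = np.array(tris, dtype=np.int64)
    region = np.array(region, dtype=np.int8)

    def vedges(i, j0, j1):
        return np.array([(node_id[i, j], node_id[i, j + 1]) for j in range(j0, j1)])

    def hedges(j, i0, i1):
        return np.array([(node_id[i, j], node_id[i + 1, j]) for i in range(i0, i1)])

    edges = {
        "axis": vedges(0, 0, j_fill),
        "outer_surface": np.vstack([vedges(nr - 1, j_bot - nbz, nz - 1),
                                    hedges(0, 0, nr - 1)]),
        "free_surface": hedges(j_fill, 0, i_ri),
        "wall_cpa_interface": vedges(i_ri, j_bot, j_fill),
        "cpa_bottom_interface": hedges(j_bot, 0, i_ri),
        "wall_top": hedges(nz - 1, i_ri, nr - 1),
        "wall_inner_exposed": vedges(i_ri, j_fill, nz - 1),
    }

    surface_nodes = np.array([node_id[i, j_fill] for i in range(i_ri + 1)])
    cpa_grid = node_id[:i_ri + 1, j_bot:j_fill + 1].copy()
    structure = {
        "surface_nodes": surface_nodes,
        "cpa_grid": cpa_grid,                       # (i_ri+1, nzc+1) node ids
        "column_radii": r_lines[:i_ri + 1].copy(),
        "geometry": geometry,
    }
    mesh = AxisymMesh(nodes, tris, region, edges, structure)
    if np.any(mesh.element_areas() <= 0):
        raise RuntimeError("mesh generator produced inverted elements")
    return mesh


def build_box_mesh(width: float, height: float, nx: int, ny: int,
                   region: int = CPA) -> AxisymMesh:
    """Plain rectangle mesh for verification problems (planar or axisym).

    Tags: ``left``, ``right``, ``bottom``, ``top`` plus an alias
    ``free_surface`` = top and ``axis`` = left.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    node_id = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
    rr, zz = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])
    tris = []
    for i in range(nx):
        for j in range(ny):
            n00, n10 = node_id[i, j], node_id[i + 1, j]
            n11, n01 = node_id[i + 1, j + 1], node_id[i, j + 1]
            if (i + j) % 2 == 0:
                tris += [(n00, n10, n11), (n00, n11, n01)]
            else:
                tris += [(n00, n10, n01), (n10, n11, n01)]
    tris = np.array(tris, dtype=np.int64)
    regions = np.full(len(tris), region, dtype=np.int8)
    edges = {
        "left": np.array([(node_id[0, j], node_id[0, j + 1]) for j in range(ny)]),
        "right": np.array([(node_id[nx, j], node_id[nx, j + 1]) for j in range(ny)]),
        "bottom": np.array([(node_id[i, 0], node_id[i + 1, 0]) for i in range(nx)]),
        "top": np.array([(node_id[i, ny], node_id[i + 1, ny]) for i in range(nx)]),
    }
    edges["free_surface"] = edges["top"]
    edges["axis"] = edges["left"]
    structure = {"surface_nodes": np.array([node_id[i, ny] for i in range(nx + 1)]),
                 "cpa_grid": node_id.copy(),
                 "column_radii": xs.copy()}
    return AxisymMesh(nodes, tris, regions, edges, structure)


# ---------------------------------------------------------------------------
# quality metric: q = 2 r_in / r_circ, normalized to 1 for equilateral
# (r_in = 2A / perimeter, r_circ = abc / 4A  ->  q = 16 A^2 / (p * a b c))
# ---------------------------------------------------------------------------

def element_quality(mesh: AxisymMesh) -> np.ndarray:
    p = mesh.nodes[mesh.tris]
    a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    area = mesh.element_areas()
    denom = (a + b + c) * a * b * c
    q = 16.0 * np.sign(area) * area**2 / np.maximum(denom, 1e-300)
    return np.clip(q, 0.0, 1.0)


def mesh_quality(mesh: AxisymMesh) -> float:
    """Minimum element shape quality in [0, 1] (1 = equilateral)."""
    return float(element_quality(mesh).min())


def cpa_volume(mesh: AxisymMesh) -> float:
    """CPA volume 2 pi int r dA over the CPA region, m^3."""
    cpa = mesh.region == CPA
    area, _ = tri_geometry(mesh.nodes, mesh.tris[cpa])
    r_q = quad_points(mesh.nodes, mesh.tris[cpa])[..., 0]
    return float(2.0 * np.pi * np.sum(area * (r_q * QW).sum(axis=1)))


def surface_normals(mesh: AxisymMesh) -> np.ndarray:
    """Outward unit normals at free-surface nodes (ordered as the nodes).

    Edge normals point out of the CPA (away from the opposing vertex of the
    adjacent element); node normals average the adjacent edge normals.  The
    normal at the axis node is forced vertical (symmetry).
    """
    surf = mesh.free_surface_nodes
    pos = {n: i for i, n in enumerate(surf)}
    acc = np.zeros((len(surf), 2))
    edge_nodes = set(surf.tolist())
    for e in mesh.tris[mesh.region == CPA]:
        verts = e.tolist()
        onsurf = [v in edge_nodes for v in verts]
        if sum(onsurf) != 2:
            continue
        (i1, i2) = [v for v, o in zip(verts, onsurf) if o]
        (i3,) = [v for v, o in zip(verts, onsurf) if not o]
        t = mesh.nodes[i2] - mesh.nodes[i1]
        n = np.array([t[1], -t[0]])
        if np.dot(n, mesh.nodes[i3] - mesh.nodes[i1]) > 0:
            n = -n
        ln = np.linalg.norm(t)
        for v in (i1, i2):
            acc[pos[v]] += n / max(np.linalg.norm(n), 1e-300) * ln
    nrm = np.linalg.norm(acc, axis=1, keepdims=True)
    normals = acc / np.maximum(nrm, 1e-300)
    on_axis = mesh.nodes[surf, 0] <= 1e-14
    normals[on_axis] = [0.0, 1.0]
    return normals


def _cpa_node_graph(mesh: AxisymMesh):
    tris = mesh.cpa_tris
    n = mesh.nodes.shape[0]
    pairs = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    data = np.ones(len(pairs))
    adj = sp.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    adj = adj + adj.T
    adj.data[:] = 1.0
    return adj.tocsr()


def move_free_surface(mesh: AxisymMesh, surface_normal_velocity: np.ndarray,
                      dt: float, quality_floor: float = 0.0) -> AxisymMesh:
    """Advance the free surface by v_n dt along the local normals.

    Interior CPA nodes follow by Laplacian smoothing with wall, bottom and
    surface displacements as Dirichlet data; axis nodes keep r = 0 but may
    slide in z.  The surface-wall contact node is pinned.  Raises
    :class:`RemeshRequired` if the motion inverts elements or drops the
    minimum quality below ``quality_floor``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    surf = mesh.free_surface_nodes
    vn = np.asarray(surface_normal_velocity, dtype=float)
    if vn.shape != surf.shape:
        raise ValueError("one normal velocity per free-surface node required")
    normals = surface_normals(mesh)
    disp_surf = vn[:, None] * dt * normals
    disp_surf[-1] = 0.0                       # pinned contact line at the wall
    on_axis = mesh.nodes[surf, 0] <= 1e-14
    disp_surf[on_axis, 0] = 0.0

    n = mesh.nodes.shape[0]
    cpa_nodes = np.unique(mesh.cpa_tris)
    fixed0 = np.concatenate([mesh.nodes_of("wall_cpa_interface"),
                             mesh.nodes_of("cpa_bottom_interface")])
    axis_nodes = np.intersect1d(mesh.nodes_of("axis"), cpa_nodes)

    disp = np.zeros((n, 2))
    disp[surf] = disp_surf
    prescribed_r = np.zeros(n, dtype=bool)
    prescribed_z = np.zeros(n, dtype=bool)
    prescribed_r[surf] = prescribed_z[surf] = True
    prescribed_r[fixed0] = prescribed_z[fixed0] = True
    prescribed_r[axis_nodes] = True           # r stays 0; z smoothed

    adj = _cpa_node_graph(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    new_nodes = mesh.nodes.copy()
    for comp, prescribed in ((0, prescribed_r), (1, prescribed_z)):
        free = np.setdiff1d(cpa_nodes, np.nonzero(prescribed)[0])
        if len(free) == 0:
            continue
        a = lap[free][:, free].tocsc()
        rhs = -lap[free][:, :] @ disp[:, comp] + a @ disp[free, comp]
        disp[free, comp] = spla.spsolve(a, rhs)
    new_nodes += disp

    out = AxisymMesh(new_nodes, mesh.tris, mesh.region, mesh.edges, mesh.structure)
    area, _ = tri_geometry(out.nodes, out.tris)
    if np.any(area <= 0):
        raise RemeshRequired("mesh motion inverted elements")
    if quality_floor > 0 and mesh_quality(out) < quality_floor:
        raise RemeshRequired(
            f"mesh quality {mesh_quality(out):.3f} below floor {quality_floor}")
    return out


def redistribute_columns(mesh: AxisymMesh):
    """Rebuild CPA node positions along the original radial columns.

    The free surface is re-sampled as a single-valued graph z = eta(r) at
    the original column radii; each column's nodes are redistributed
    uniformly between the container bottom and eta(r).  Connectivity and
    tags are unchanged.  Returns ``(new_mesh, interpolate)`` where
    ``interpolate(field)`` maps a nodal field onto the new node positions
    (1-D linear interpolation along each column; non-CPA nodes unchanged).
    """
    grid = mesh.structure["cpa_grid"]
    radii = mesh.structure["column_radii"]
    surf = mesh.free_surface_nodes
    order = np.argsort(mesh.nodes[surf, 0])
    r_s = mesh.nodes[surf[order], 0]
    z_s = mesh.nodes[surf[order], 1]
    eta = np.interp(radii, r_s, z_s)

    new_nodes = mesh.nodes.copy()
    old_z_cols, new_z_cols = [], []
    n_rows = grid.shape[1]
    fracs = np.linspace(0.0, 1.0, n_rows)
    for ic in range(grid.shape[0]):
        ids = grid[ic]
        old_z = mesh.nodes[ids, 1].copy()
        new_z = fracs * eta[ic]
        new_nodes[ids, 0] = radii[ic]
        new_nodes[ids, 1] = new_z
        old_z_cols.append((ids, old_z))
        new_z_cols.append(new_z)

    out = AxisymMesh(new_nodes, mesh.tris, mesh.region, mesh.edges, mesh.structure)
    area, _ = tri_geometry(out.nodes, out.tris)
    if np.any(area <= 0):
        raise RemeshRequired("column redistribution failed (inverted elements)")

    def interpolate(field: np.ndarray) -> np.ndarray:
        new = np.asarray(field, dtype=float).copy()
        for (ids, old_z), new_z in zip(old_z_cols, new_z_cols):
            srt = np.argsort(old_z)
            new[ids] = np.interp(new_z, old_z[srt], field[ids][srt])
        return new

    return out, interpolate
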