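"""Quasi-static creeping-flow solver on the CPA region.

Solves the axisymmetric Stokes system with temperature-dependent viscosity
and density,

    div[ -p I + mu (grad v + grad v') - (2/3) mu (div v) I ] + rho(T) g = 0
    div v = -(1/rho)(drho/dT)(DT/Dt)

i.e. mass conservation with rho = rho(T) turned into a thermal-contraction
volume source.  The transient term rho dv/dt is dropped by default (the
creeping-flow regime makes each step quasi-static).  Boundary conditions:
zero total traction on the free surface (surface tension neglected),
no slip on all CPA-wall interfaces, symmetry (v_r = 0, zero shear) on the
axis.

Discretization: continuous P1 velocity and pressure with pressure
(Brezzi-Pitkaranta / PSPG-type) stabilization, delta_K = c h_K^2 / mu_K,
including the body-force term so that hydrostatic equilibrium is captured
exactly.  Element viscosity is the geometric mean of (capped) nodal values
— the natural interpolation for an exponential viscosity law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import QP, QW, tri_geometry, quad_points
from .geometry import AxisymMesh, CPA, mesh_quality, surface_normals
from .materials import MaterialSet

__all__ = ["FlowField", "solve_creeping_flow", "free_surface_normal_velocity",
           "surface_traction_residual", "surface_flux"]

log = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2, acting in -z


class FlowSolveError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Nodal velocity (m/s) and pressure (Pa) on the full mesh.

    Values are zero outside the CPA region; ``in_cpa`` marks nodes that
    carry actual unknowns.
    """

    vr: np.ndarray
    vz: np.ndarray
    p: np.ndarray
    in_cpa: np.ndarray
    info: dict = field(default_factory=dict)

    @property
    def velocity(self) -> np.ndarray:
        return np.column_stack([self.vr, self.vz])


def _element_viscosity(model, T_nodes, tris_local):
    mu_node = model(T_nodes)
    mu_node = np.atleast_1d(mu_node)
    return np.exp(np.log(mu_node[tris_local]).mean(axis=1))


def solve_creeping_flow(mesh: AxisymMesh, T: np.ndarray, dTdt: np.ndarray,
                        materials: MaterialSet, gravity: float = GRAVITY, *,
                        axisymmetric: bool = True,
                        arrest_threshold: float | None = None,
                        viscosity_elem: np.ndarray | None = None,
                        source_elem: np.ndarray | None = None,
                        noslip_tags=("wall_cpa_interface", "cpa_bottom_interface"),
                        axis_tag: str = "axis",
                        c_stab: float = 0.1,
                        surface_dt: float | None = None) -> FlowField:
    """Solve one quasi-static Stokes problem; returns a :class:`FlowField`.

    ``viscosity_elem`` / ``source_elem`` optionally override the per-element
    viscosity and volume source on the CPA elements (used by the
    thermo-mechanics variant to switch arrested material to its solid
    response).  ``arrest_threshold`` (Pa.s), when given, pins v = 0 at nodes
    whose (capped) viscosity reaches the threshold, excluding fully arrested
    material from the flow system.

    ``surface_dt`` enables the implicit free-surface stabilization used by
    the time loop: moving the surface by v dt perturbs the hydrostatic
    load by -rho g (v.n dt) n, and treating that restoring traction
    implicitly adds the positive semi-definite boundary form
    ``dt int rho g (v.n)(w.n) ds`` on the free surface.  Without it an
    explicit surface update is unstable at any practical step size while
    the CPA is still watery (the gravity-leveling time scale is
    mu / (rho g R), microseconds at millipascal-second viscosity).
    """
    T = np.asarray(T, dtype=float)
    dTdt = np.asarray(dTdt, dtype=float)
    n_all = mesh.nodes.shape[0]
    tris = mesh.cpa_tris
    cpa_nodes = np.unique(tris)
    n = len(cpa_nodes)
    glob2loc = -np.ones(n_all, dtype=np.int64)
    glob2loc[cpa_nodes] = np.arange(n)
    tl = glob2loc[tris]                                  # (M, 3) local

    nodes = mesh.nodes
    area, g = tri_geometry(nodes, tris)
    xq = quad_points(nodes, tris)                        # (M, Q, 2)
    rq = xq[..., 0] if axisymmetric else np.ones(xq.shape[:2])

    cpa = materials.cpa
    if viscosity_elem is None:
        mu_e = _element_viscosity(cpa.viscosity, T, tris)
    else:
        mu_e = np.asarray(viscosity_elem, dtype=float)
    rho_node = np.atleast_1d(cpa.density(T))
    if source_elem is None:
        drho = np.atleast_1d(cpa.density.derivative()(T))
        g_node = -(drho / rho_node) * dTdt               # volume source, 1/s
        g_q = np.einsum("qi,mi->mq", QP, g_node[tris])
    else:
        g_q = np.repeat(np.asarray(source_elem, float)[:, None], QP.shape[0], axis=1)
    rho_q = np.einsum("qi,mi->mq", QP, rho_node[tris])

    m_tot = tris.shape[0]
    Ke = np.zeros((m_tot, 6, 6))
    Ge = np.zeros((m_tot, 6, 3))
    Ce = np.zeros((m_tot, 3, 3))
    fe = np.zeros((m_tot, 6))
    he = np.zeros((m_tot, 3))                            # continuity rhs
    hg = np.zeros((m_tot, 3))                            # stab body-force rhs

    h_e = np.sqrt(2.0 * np.abs(area))
    delta = c_stab * h_e**2 / mu_e

    mvec = np.array([1.0, 1.0, 1.0, 0.0])
    base_D = np.diag([2.0, 2.0, 2.0, 1.0]) - (2.0 / 3.0) * np.outer(mvec, mvec)

    for q in range(QP.shape[0]):
        wq = QW[q]
        phi = QP[q]                                      # (3,)
        r = rq[:, q]
        scale = wq * area * r                            # (M,)
        B = np.zeros((m_tot, 4, 6))
        B[:, 0, 0:3] = g[:, :, 0]                        # eps_rr from ur
        B[:, 1, 3:6] = g[:, :, 1]                        # eps_zz from uz
        if axisymmetric:
            B[:, 2, 0:3] = phi[None, :] / r[:, None]     # eps_theta from ur
        B[:, 3, 0:3] = g[:, :, 1]                        # gamma_rz
        B[:, 3, 3:6] = g[:, :, 0]
        divB = np.einsum("a,mak->mk", mvec, B)           # (M, 6)
        Ke += np.einsum("m,mak,ab,mbl->mkl", scale * mu_e, B, base_D, B)
        Ge -= np.einsum("m,mk,a->mka", scale, divB, phi)
        he += np.einsum("m,a->ma", scale * g_q[:, q], phi)
        fe[:, 3:6] += (scale * rho_q[:, q] * (-gravity))[:, None] * phi[None, :]
        hg += np.einsum("m,ma->ma", scale * delta * rho_q[:, q] * (-gravity),
                        g[:, :, 1])
    # stabilization matrix: delta int grad(q).grad(p) w dA
    wsum = (rq * QW).sum(axis=1)
    gg = np.einsum("mia,mja->mij", g, g)
    Ce += (delta * area * wsum)[:, None, None] * gg

    # implicit free-surface restoring term (see docstring)
    surf_rows, surf_cols, surf_vals = [], [], []
    if surface_dt is not None and "free_surface" in mesh.edges:
        for e0, e1 in mesh.edges["free_surface"]:
            l0, l1 = glob2loc[e0], glob2loc[e1]
            if l0 < 0 or l1 < 0:
                continue
            p0, p1 = nodes[e0], nodes[e1]
            tvec = p1 - p0
            length = np.hypot(tvec[0], tvec[1])
            nvec = np.array([tvec[1], -tvec[0]])
            if nvec[1] < 0:
                nvec = -nvec
            nvec /= max(np.linalg.norm(nvec), 1e-300)
            dofs = np.array([l0, l1, n + l0, n + l1])
            block = np.zeros((4, 4))
            for s, wq in ((0.5 - 0.5 / np.sqrt(3), 0.5),
                          (0.5 + 0.5 / np.sqrt(3), 0.5)):
                phi = np.array([1 - s, s])
                r_s = (1 - s) * p0[0] + s * p1[0] if axisymmetric else 1.0
                rho_s = (1 - s) * rho_node[e0] + s * rho_node[e1]
                Nv = np.concatenate([phi * nvec[0], phi * nvec[1]])
                block += (surface_dt * rho_s * gravity * wq * length * r_s) \
                    * np.outer(Nv, Nv)
            surf_rows.append(np.repeat(dofs, 4))
            surf_cols.append(np.tile(dofs, 4))
            surf_vals.append(block.ravel())

    # ---- scatter to global triplets ------------------------------------
    ndof = 3 * n
    du = np.concatenate([tl, n + tl], axis=1)            # (M, 6)
    dp = 2 * n + tl                                      # (M, 3)

    def triplets(rows_dofs, cols_dofs, blocks):
        rw = np.repeat(rows_dofs, cols_dofs.shape[1], axis=1).ravel()
        cl = np.tile(cols_dofs, (1, rows_dofs.shape[1])).ravel()
        return rw, cl, blocks.reshape(len(blocks), -1).ravel()

    rows, cols, vals = [], [], []
    for rd, cd, bl in ((du, du, Ke), (du, dp, Ge),
                       (dp, du, np.transpose(Ge, (0, 2, 1))), (dp, dp, -Ce)):
        r_, c_, v_ = triplets(rd, cd, bl)
        rows.append(r_)
        cols.append(c_)
        vals.append(v_)
    rows.extend(surf_rows)
    cols.extend(surf_cols)
    vals.extend(surf_vals)

    rhs = np.zeros(ndof)
    np.add.at(rhs, du.ravel(), fe.ravel())
    np.add.at(rhs, dp.ravel(), (-he - hg).ravel())

    # ---- Dirichlet dofs (all zero-valued) -------------------------------
    fixed = np.zeros(ndof, dtype=bool)
    for tag in noslip_tags:
        if tag in mesh.edges:
            loc = glob2loc[np.unique(mesh.edges[tag])]
            loc = loc[loc >= 0]
            fixed[loc] = True
            fixed[n + loc] = True
    if axisymmetric and axis_tag in mesh.edges:
        loc = glob2loc[np.unique(mesh.edges[axis_tag])]
        loc = loc[loc >= 0]
        fixed[loc] = True                                # v_r = 0 on axis
    n_arrested = 0
    if arrest_threshold is not None:
        mu_node_cap = np.atleast_1d(cpa.viscosity(T))[cpa_nodes]
        arr = mu_node_cap >= arrest_threshold
        n_arrested = int(np.count_nonzero(arr))
        loc = np.nonzero(arr)[0]
        fixed[loc] = True
        fixed[n + loc] = True

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    keep = ~(fixed[rows] | fixed[cols])
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    fixed_idx = np.nonzero(fixed)[0]
    rows = np.concatenate([rows, fixed_idx])
    cols = np.concatenate([cols, fixed_idx])
    vals = np.concatenate([vals, np.ones(len(fixed_idx))])
    rhs[fixed_idx] = 0.0

    A = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsc()
    # symmetric diagonal equilibration: the viscosity contrast spans many
    # decades, which would otherwise wreck the factorization scaling
    d = np.abs(A.diagonal())
    d[d == 0] = 1.0
    s = 1.0 / np.sqrt(d)
    S = sp.diags(s)
    try:
        lu = spla.splu((S @ A @ S).tocsc())
        x = s * lu.solve(s * rhs)
    except Exception as err:
        raise FlowSolveError(
            f"Stokes solve failed: {err}; viscosity contrast "
            f"{mu_e.max() / mu_e.min():.2e}, min mesh quality "
            f"{mesh_quality(mesh):.3f}") from err
    if not np.all(np.isfinite(x)):
        raise FlowSolveError(
            "Stokes solve produced non-finite values; viscosity contrast "
            f"{mu_e.max() / mu_e.min():.2e}, min mesh quality "
            f"{mesh_quality(mesh):.3f}")

    vr = np.zeros(n_all)
    vz = np.zeros(n_all)
    p = np.zeros(n_all)
    vr[cpa_nodes] = x[:n]
    vz[cpa_nodes] = x[n:2 * n]
    p[cpa_nodes] = x[2 * n:]
    in_cpa = np.zeros(n_all, dtype=bool)
    in_cpa[cpa_nodes] = True
    info = {"mu_min": float(mu_e.min()), "mu_max": float(mu_e.max()),
            "n_arrested_nodes": n_arrested}
    return FlowField(vr, vz, p, in_cpa, info)


def free_surface_normal_velocity(flow: FlowField, mesh: AxisymMesh) -> np.ndarray:
    """v . n at each free-surface node (outward normal); contact node 0."""
    surf = mesh.free_surface_nodes
    normals = surface_normals(mesh)
    v = flow.velocity[surf]
    vn = np.einsum("na,na->n", v, normals)
    vn[-1] = 0.0
    return vn


def surface_flux(flow: FlowField, mesh: AxisymMesh, axisymmetric: bool = True) -> float:
    """Volume flux through the free surface, int 2 pi r v.n ds (m^3/s)."""
    surf_edges = mesh.edges["free_surface"]
    p0 = mesh.nodes[surf_edges[:, 0]]
    p1 = mesh.nodes[surf_edges[:, 1]]
    t = p1 - p0
    length = np.hypot(t[:, 0], t[:, 1])
    # outward normal: free surface is the top of the CPA, normal ~ +z
    nvec = np.column_stack([t[:, 1], -t[:, 0]])
    flip = nvec[:, 1] < 0
    nvec[flip] = -nvec[flip]
    nvec /= np.maximum(np.linalg.norm(nvec, axis=1, keepdims=True), 1e-300)
    total = 0.0
    v0 = flow.velocity[surf_edges[:, 0]]
    v1 = flow.velocity[surf_edges[:, 1]]
    for s, wq in ((0.5 - 0.5 / np.sqrt(3), 0.5), (0.5 + 0.5 / np.sqrt(3), 0.5)):
        vq = (1 - s) * v0 + s * v1
        rqv = (1 - s) * p0[:, 0] + s * p1[:, 0]
        w = 2 * np.pi * rqv if axisymmetric else np.ones_like(rqv)
        total += np.sum(wq * length * w * np.einsum("ea,ea->e", vq, nvec))
    return float(total)


def _edge_to_element(mesh: AxisymMesh):
    lookup = {}
    for idx, tri in enumerate(mesh.tris):
        if mesh.region[idx] != CPA:
            continue
        for a, b in ((0, 1), (1, 2), (2, 0)):
            lookup[frozenset((tri[a], tri[b]))] = idx
    return lookup


def surface_traction_residual(flow: FlowField, mesh: AxisymMesh, T: np.ndarray,
                              materials: MaterialSet,
                              axisymmetric: bool = True,
                              exclude_radius_fraction: float = 1.0) -> float:
    """Max |traction| (Pa) of the discrete stress on the free surface.

    A verification diagnostic: the traction-free condition is imposed
    weakly, so the pointwise residual is nonzero but should shrink under
    refinement where the solution is smooth.  The pinned contact line at
    the wall is a classic corner stress singularity (no-slip meeting a
    traction-free surface): the pointwise traction there grows under
    refinement, so convergence studies should pass
    ``exclude_radius_fraction < 1`` to look only at edge midpoints with
    r below that fraction of the surface radius.
    """
    lookup = _edge_to_element(mesh)
    cpa = materials.cpa
    worst = 0.0
    _, grads = tri_geometry(mesh.nodes, mesh.tris)
    surf_edges = mesh.edges["free_surface"]
    r_max = mesh.nodes[np.unique(surf_edges), 0].max()
    for e0, e1 in surf_edges:
        mid_r = 0.5 * (mesh.nodes[e0, 0] + mesh.nodes[e1, 0])
        if mid_r > exclude_radius_fraction * r_max:
            continue
        idx = lookup.get(frozenset((e0, e1)))
        if idx is None:
            continue
        tri = mesh.tris[idx]
        g = grads[idx]
        vloc = flow.velocity[tri]
        L = np.einsum("ia,ib->ab", vloc, g)              # L[a,b] = d v_a / d x_b
        mid = 0.5 * (mesh.nodes[e0] + mesh.nodes[e1])
        phi_mid = _p1_barycentric(mesh.nodes[tri], mid)
        p_mid = float(phi_mid @ flow.p[tri])
        mu = float(np.exp(np.log(np.atleast_1d(cpa.viscosity(T))[tri]).mean()))
        eps = 0.5 * (L + L.T)
        div = np.trace(L)
        if axisymmetric and mid[0] > 0:
            v_r_mid = float(phi_mid @ vloc[:, 0])
            div += v_r_mid / mid[0]
        sig = -p_mid * np.eye(2) + 2 * mu * eps - (2.0 / 3.0) * mu * div * np.eye(2)
        t = mesh.nodes[e1] - mesh.nodes[e0]
        nvec = np.array([t[1], -t[0]])
        if nvec[1] < 0:
            nvec = -nvec
        nvec /= max(np.linalg.norm(nvec), 1e-300)
        worst = max(worst, float(np.linalg.norm(sig @ nvec)))
    return worst


def _p1_barycentric(tri_nodes: np.ndarray, x: np.ndarray) -> np.ndarray:
    m = np.vstack([tri_nodes.T, np.ones(3)])
    return np.linalg.solve(m, np.array([x[0], x[1], 1.0]))
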