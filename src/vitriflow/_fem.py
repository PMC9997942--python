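"""Shared linear-triangle finite-element machinery.

All assembly routines support two coordinate weights: axisymmetric
(cylindrical (r, z), integrand weighted by r; the 2*pi factor is dropped
consistently from both sides of every system) and planar (weight 1, used by
verification benchmarks such as the Robin-cooled slab).

Quadrature is the 3-point interior rule (degree-2 exact); its points are
strictly inside each triangle, so r > 0 at every quadrature point of any
valid axisymmetric element and terms like u_r / r stay finite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# barycentric coordinates / weights of the degree-2 interior rule
QP = np.array([[2 / 3, 1 / 6, 1 / 6],
               [1 / 6, 2 / 3, 1 / 6],
               [1 / 6, 1 / 6, 2 / 3]])
QW = np.array([1 / 3, 1 / 3, 1 / 3])

# 2-point Gauss rule on an edge, in the edge parameter [0, 1]
EDGE_QP = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
EDGE_QW = np.array([0.5, 0.5])


def tri_geometry(nodes: np.ndarray, tris: np.ndarray):
    """Signed areas and constant P1 basis gradients.

    Returns ``(area (M,), grads (M, 3, 2))`` where ``grads[e, i]`` is the
    gradient of the hat function of local node ``i`` on element ``e``.
    """
    p = nodes[tris]                      # (M, 3, 2)
    r = p[..., 0]
    z = p[..., 1]
    det = (r[:, 1] - r[:, 0]) * (z[:, 2] - z[:, 0]) \
        - (r[:, 2] - r[:, 0]) * (z[:, 1] - z[:, 0])
    area = 0.5 * det
    g = np.empty(p.shape)
    # grad phi_i = ( (z_j - z_k), (r_k - r_j) ) / det  with (i, j, k) cyclic;
    # degenerate (zero-area) elements yield non-finite gradients, which the
    # quality metric tolerates and solvers reject via the area check
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            g[:, i, 0] = (z[:, j] - z[:, k]) / det
            g[:, i, 1] = (r[:, k] - r[:, j]) / det
    return area, g


def quad_points(nodes: np.ndarray, tris: np.ndarray):
    """Physical coordinates of the interior quadrature points, (M, Q, 2)."""
    p = nodes[tris]
    return np.einsum("qi,mij->mqj", QP, p)


def elem_weight(nodes, tris, axisymmetric: bool):
    """Per-element, per-quadrature-point coordinate weight (r or 1)."""
    if axisymmetric:
        return quad_points(nodes, tris)[..., 0]
    m, _ = tris.shape
    return np.ones((m, QP.shape[0]))


def assemble_csr(tris: np.ndarray, ke: np.ndarray, n_nodes: int) -> sp.csr_matrix:
    """Scatter per-element (M, 3, 3) blocks into a CSR matrix."""
    m = tris.shape[0]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    a = sp.coo_matrix((ke.reshape(m, 9).ravel(), (rows, cols)),
                      shape=(n_nodes, n_nodes))
    return a.tocsr()


def stiffness(nodes, tris, coeff_elem, axisymmetric=True) -> sp.csr_matrix:
    """Assemble ``int coeff grad(u).grad(v) w dA`` (coeff constant/element)."""
    area, g = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    wsum = (w * QW).sum(axis=1)                       # per-element mean weight
    gg = np.einsum("mia,mja->mij", g, g)
    ke = (coeff_elem * area * wsum)[:, None, None] * gg
    return assemble_csr(tris, ke, nodes.shape[0])


def lumped_mass(nodes, tris, coeff_elem, axisymmetric=True) -> np.ndarray:
    """Row-sum lumped mass vector of ``int coeff u v w dA``."""
    area, _ = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    # row sum of consistent mass: int coeff phi_i w dA
    phi_w = np.einsum("mq,qi,q->mi", w, QP, QW)       # (M, 3)
    me = coeff_elem[:, None] * area[:, None] * phi_w
    out = np.zeros(nodes.shape[0])
    np.add.at(out, tris.ravel(), me.ravel())
    return out


def advection(nodes, tris, coeff_elem, vel_nodes, axisymmetric=True) -> sp.csr_matrix:
    """Assemble ``int coeff (v . grad u) phi_i w dA`` with nodal velocity."""
    area, g = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    v_e = vel_nodes[tris]                             # (M, 3, 2)
    v_q = np.einsum("qi,mia->mqa", QP, v_e)           # (M, Q, 2)
    vg = np.einsum("mqa,mja->mqj", v_q, g)            # v . grad(phi_j)
    ke = np.einsum("m,mq,q,qi,mqj->mij", coeff_elem * area, w, QW, QP, vg)
    return assemble_csr(tris, ke, nodes.shape[0])


def streamline_diffusion(nodes, tris, coeff_elem, vel_nodes, diff_elem,
                         axisymmetric=True):
    """Artificial streamline diffusion for advection-dominated elements.

    Adds ``tau (v.grad u)(v.grad v)`` on elements whose cell Peclet number
    ``|v| h coeff / (2 diff)`` exceeds 1.  Returns ``(matrix, n_active)``.
    """
    area, g = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    wsum = (w * QW).sum(axis=1)
    v_e = vel_nodes[tris].mean(axis=1)                # element velocity
    speed = np.hypot(v_e[:, 0], v_e[:, 1])
    h = np.sqrt(2.0 * np.abs(area))
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(diff_elem > 0, speed * h * coeff_elem / (2 * diff_elem), np.inf)
    active = (pe > 1.0) & (speed > 0)
    n_active = int(np.count_nonzero(active))
    if not n_active:
        return sp.csr_matrix((nodes.shape[0],) * 2), 0
    tau = np.where(active, h / (2 * np.maximum(speed, 1e-300))
                   * (1.0 - 1.0 / np.maximum(pe, 1.0)), 0.0)
    vg = np.einsum("ma,mja->mj", v_e, g)              # (M, 3)
    ke = (tau * coeff_elem**2 * area * wsum)[:, None, None] \
        * np.einsum("mi,mj->mij", vg, vg)
    return assemble_csr(tris, ke, nodes.shape[0]), n_active


def robin_edges(nodes, edges, h, axisymmetric=True):
    """Robin boundary pieces ``int h u v w ds`` and ``int h v w ds``.

    Returns ``(matrix, load)`` so that the condition ``-n.k grad T = h (T -
    T_inf)`` contributes ``matrix @ T - load * T_inf`` to the residual.
    """
    n = nodes.shape[0]
    p0 = nodes[edges[:, 0]]
    p1 = nodes[edges[:, 1]]
    length = np.hypot(*(p1 - p0).T)
    ke = np.zeros((edges.shape[0], 2, 2))
    fe = np.zeros((edges.shape[0], 2))
    for s, wq in zip(EDGE_QP, EDGE_QW):
        phi = np.array([1 - s, s])
        w = (1 - s) * p0[:, 0] + s * p1[:, 0] if axisymmetric else np.ones(len(p0))
        ke += (h * wq * length * w)[:, None, None] * np.outer(phi, phi)
        fe += (h * wq * length * w)[:, None] * phi
    rows = np.repeat(edges, 2, axis=1).ravel()
    cols = np.tile(edges, (1, 2)).ravel()
    mat = sp.coo_matrix((ke.reshape(-1, 4).ravel(), (rows, cols)), shape=(n, n)).tocsr()
    load = np.zeros(n)
    np.add.at(load, edges.ravel(), fe.ravel())
    return mat, load


def load_vector(nodes, tris, f_nodes, axisymmetric=True) -> np.ndarray:
    """Assemble ``int f phi_i w dA`` for a nodal field f."""
    area, _ = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    f_q = np.einsum("qi,mi->mq", QP, f_nodes[tris])
    fe = np.einsum("m,mq,mq,q,qi->mi", area, f_q, w, QW, QP)
    out = np.zeros(nodes.shape[0])
    np.add.at(out, tris.ravel(), fe.ravel())
    return out


def nodal_gradient(nodes, tris, field, axisymmetric=True) -> np.ndarray:
    """Weight-averaged nodal gradient of a P1 field, (N, 2)."""
    area, g = tri_geometry(nodes, tris)
    w = elem_weight(nodes, tris, axisymmetric)
    wsum = (w * QW).sum(axis=1) * area
    grad_e = np.einsum("mi,mia->ma", field[tris], g)  # (M, 2)
    num = np.zeros((nodes.shape[0], 2))
    den = np.zeros(nodes.shape[0])
    np.add.at(num, tris.ravel(),
              np.repeat(grad_e, 3, axis=0) * wsum.repeat(3)[:, None])
    np.add.at(den, tris.ravel(), wsum.repeat(3))
    return num / np.maximum(den, 1e-300)[:, None]


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray,
                    values: np.ndarray | float = 0.0):
    """Impose Dirichlet values by row replacement (in place on copies)."""
    A = A.tolil(copy=True)
    b = b.copy()
    vals = np.broadcast_to(np.asarray(values, dtype=float), dofs.shape)
    A[dofs, :] = 0.0
    A[dofs, dofs] = 1.0
    b[dofs] = vals
    return A.tocsr(), b
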