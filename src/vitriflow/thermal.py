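"""Transient conduction-advection solver for the cuvette + CPA domain.

Solves rho c_p (dT/dt + v . grad T) = div(k grad T) with a single
conforming temperature field over both regions (temperature and flux
continuity at the wall-CPA interface are automatic), a Robin condition
-n . k grad T = h (T_surface - T_chamber) on the exterior surfaces, and a
zero-flux symmetry condition on the axis.

Time integration is backward Euler with a lumped mass matrix; on the
structured right-triangle meshes used here this yields a discrete maximum
principle for pure conduction.  Properties are evaluated at the element
mean of the previous temperature field (one-step property lag).  Streamline
diffusion is added only on elements whose cell Peclet number exceeds one
(logged); for the creeping flows of interest Pe << 1 and the term stays
inactive.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .geometry import AxisymMesh, REGION_NAMES
from .materials import MaterialSet

__all__ = ["step_temperature", "material_derivative_T", "default_robin_map"]

log = logging.getLogger(__name__)


def default_robin_map(materials: MaterialSet) -> dict:
    """Boundary tag -> heat transfer coefficient (W/m^2-degC).

    Forced convection on the outer cuvette surface (side and bottom); free
    convection on the CPA free surface and the exposed wall surfaces above
    the fill line.  All reference the same chamber temperature.
    """
    return {
        "outer_surface": materials.h_forced,
        "free_surface": materials.h_free,
        "wall_top": materials.h_free,
        "wall_inner_exposed": materials.h_free,
    }


def _element_props(mesh: AxisymMesh, T_old: np.ndarray, materials: MaterialSet):
    T_e = T_old[mesh.tris].mean(axis=1)
    k_e = np.empty_like(T_e)
    rhocp_e = np.empty_like(T_e)
    for code, name in REGION_NAMES.items():
        m = mesh.region == code
        if not np.any(m):
            continue
        props = materials.for_region(name)
        k_e[m] = props.conductivity(T_e[m])
        rhocp_e[m] = props.density(T_e[m]) * props.specific_heat(T_e[m])
    return k_e, rhocp_e


def step_temperature(mesh: AxisymMesh, T_old: np.ndarray,
                     velocity: np.ndarray | None, materials: MaterialSet,
                     T_chamber: float, dt: float, *,
                     axisymmetric: bool = True,
                     robin: dict | None = None,
                     stabilize: bool = True) -> np.ndarray:
    """One implicit step of the energy equation; returns the new field."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    T_old = np.asarray(T_old, dtype=float)
    if not np.all(np.isfinite(T_old)):
        raise ValueError("temperature field contains non-finite values")

    nodes, tris = mesh.nodes, mesh.tris
    k_e, rhocp_e = _element_props(mesh, T_old, materials)
    if np.all(k_e == 0.0):
        raise np.linalg.LinAlgError("all-zero conductivity: singular system")

    K = _fem.stiffness(nodes, tris, k_e, axisymmetric)
    Mlump = _fem.lumped_mass(nodes, tris, rhocp_e, axisymmetric)
    A = sp.csr_matrix(K.shape)
    if velocity is not None:
        vel = np.asarray(velocity, dtype=float)
        if np.any(vel):
            A = _fem.advection(nodes, tris, rhocp_e, vel, axisymmetric)
            if stabilize:
                S, n_act = _fem.streamline_diffusion(
                    nodes, tris, rhocp_e, vel, k_e, axisymmetric)
                if n_act:
                    log.info("streamline diffusion active on %d element(s)", n_act)
                    A = A + S

    robin = default_robin_map(materials) if robin is None else robin
    R = sp.csr_matrix(K.shape)
    load = np.zeros(nodes.shape[0])
    for tag, h in robin.items():
        if tag not in mesh.edges or h == 0.0:
            continue
        mat, vec = _fem.robin_edges(nodes, mesh.edges[tag], h, axisymmetric)
        R = R + mat
        load += vec

    lhs = sp.diags(Mlump / dt) + K + A + R
    rhs = Mlump / dt * T_old + load * T_chamber
    try:
        T_new = spla.spsolve(lhs.tocsc(), rhs)
    except Exception as err:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"temperature solve failed: {err}; k range "
            f"[{k_e.min():g}, {k_e.max():g}] W/m-degC") from err
    if not np.all(np.isfinite(T_new)):
        raise np.linalg.LinAlgError("temperature solve produced non-finite values")
    return T_new


def material_derivative_T(mesh: AxisymMesh, T_new: np.ndarray, T_old: np.ndarray,
                          velocity: np.ndarray | None, dt: float,
                          axisymmetric: bool = True) -> np.ndarray:
    """Nodal material derivative DT/Dt = (T_new - T_old)/dt + v . grad T_new."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    T_new = np.asarray(T_new, dtype=float)
    T_old = np.asarray(T_old, dtype=float)
    if T_new.shape != T_old.shape or T_new.shape[0] != mesh.nodes.shape[0]:
        raise ValueError("temperature fields must be nodal and consistent")
    out = (T_new - T_old) / dt
    if velocity is not None and np.any(velocity):
        grad = _fem.nodal_gradient(mesh.nodes, mesh.tris, T_new, axisymmetric)
        out = out + np.einsum("na,na->n", np.asarray(velocity, float), grad)
    return out
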