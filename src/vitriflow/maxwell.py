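"""Maxwell-solid stress extension (the thermo-mechanics, TM, model).

The vitrifying CPA is treated as a Maxwell material: the total strain rate
splits into elastic (Hookean), creep (S / 2 mu, deviatoric) and thermal
(alpha dT/dt I) parts.  The stress update integrates this split implicitly
at each material point:

    tr(sigma_new) = tr(sigma_old) + E/(1-2 nu) * tr(d_eps - alpha dT I)
    S_new = (S_old + 2 G dev(d_eps - alpha dT I)) / (1 + G dt / mu)

with shear modulus G = E / 2(1+nu) and Maxwell relaxation time
tau = mu / G = 2 mu (1+nu) / E.

In a TM run the TF loop is augmented: wherever the (uncapped) viscosity
reaches ``arrest_viscosity`` the material is latched as an amorphous solid
for the rest of cooling (temperature is monotone in these protocols).
Arrested elements contract with the solid thermal expansion coefficient
alpha (much smaller than the liquid's density-driven contraction) and keep
their physical, uncapped viscosity (bounded by ``solid_viscosity_cap``) so
that creep becomes negligible; the material adheres to the container walls
through the shared no-slip/continuity conditions.  Elsewhere the model is
identical to TF.  Elastic moduli are not part of the published property
set: the defaults below are placeholders, and while the TF-vs-TM
displacement comparison is insensitive to them, reported stress magnitudes
scale with E and should be read as parameter-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CPA, AxisymMesh
from .simulate import (DisplacementHistory, SimulationConfig, _run,
                       max_displacement)
from ._fem import QP, tri_geometry

__all__ = ["MaxwellParameters", "StressField", "update_stress",
           "run_tm_simulation", "tf_tm_difference"]

# tensor component order used throughout: (rr, zz, theta-theta, rz)
_I = np.array([1.0, 1.0, 1.0, 0.0])


@dataclass(frozen=True)
class MaxwellParameters:
    E: float = 1.0e9                  # Pa, placeholder (not a measured value)
    nu: float = 0.33
    alpha: float = 1.1e-5             # 1/degC, CPA solid thermal expansion
    arrest_viscosity: float = 1.0e8   # Pa.s, fluid -> solid switch
    solid_viscosity_cap: float = 1.0e12  # Pa.s, numerical bound in solid

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
        if self.arrest_viscosity <= 0 or self.solid_viscosity_cap <= 0:
            raise ValueError("viscosity thresholds must be positive")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk_factor(self) -> float:
        return self.E / (1.0 - 2.0 * self.nu)


@dataclass
class StressField:
    """Per-element stress state and accumulated strain split.

    ``sigma`` holds (rr, zz, theta, rz) components in Pa; the deviatoric
    part and trace are always consistent (S = sigma - tr(sigma)/3 I).
    """

    sigma: np.ndarray                 # (M, 4)
    eps_thermal: np.ndarray           # (M, 4) accumulated
    eps_creep: np.ndarray             # (M, 4) accumulated
    eps_elastic: np.ndarray           # (M, 4) current elastic strain

    @classmethod
    def zeros(cls, n_elements: int) -> "StressField":
        z = lambda: np.zeros((n_elements, 4))
        return cls(z(), z(), z(), z())

    @property
    def deviatoric(self) -> np.ndarray:
        tr = self.sigma[:, :3].sum(axis=1)
        return self.sigma - np.outer(tr / 3.0, _I)

    @property
    def von_mises(self) -> np.ndarray:
        s = self.deviatoric
        return np.sqrt(1.5 * (s[:, 0]**2 + s[:, 1]**2 + s[:, 2]**2
                              + 2.0 * s[:, 3]**2))


def _dev(t: np.ndarray) -> np.ndarray:
    tr = t[..., :3].sum(axis=-1)
    return t - np.multiply.outer(tr / 3.0, _I)


def update_stress(stress_old: np.ndarray, strain_increment: np.ndarray,
                  dT, dt: float, mu_local, params: MaxwellParameters) -> np.ndarray:
    """Implicit single-step Maxwell update at one or many material points.

    Arrays carry (rr, zz, theta, rz) tensor components (rz is the tensor
    shear component, not the engineering one).  Returns the new stress.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu_local = np.asarray(mu_local, dtype=float)
    if np.any(mu_local <= 0):
        raise ValueError("local viscosity must be positive")
    sig = np.atleast_2d(np.asarray(stress_old, dtype=float))
    deps = np.atleast_2d(np.asarray(strain_increment, dtype=float))
    dT = np.asarray(dT, dtype=float)

    deps_mech = deps - np.multiply.outer(params.alpha * dT, _I)
    tr_old = sig[:, :3].sum(axis=1)
    tr_new = tr_old + params.bulk_factor * deps_mech[:, :3].sum(axis=1)

    G = params.shear_modulus
    S_old = _dev(sig)
    de = _dev(deps_mech)
    denom = np.atleast_1d(1.0 + G * dt / mu_local)
    S_new = (S_old + 2.0 * G * de) / denom[:, None]
    out = S_new + np.multiply.outer(tr_new / 3.0, _I)
    return out if np.asarray(stress_old).ndim == 2 else out[0]


class _TMHooks:
    """State and callbacks threading the Maxwell solid into the TF loop."""

    def __init__(self, config: SimulationConfig, params: MaxwellParameters):
        self.config = config
        self.params = params
        self.solid = None             # latched per-CPA-element solid mask
        self.stress = None            # StressField over CPA elements
        self.stress_history = []      # (t, von Mises max) checkpoints
        self.t = 0.0

    # -- flow-solve overrides -------------------------------------------
    def flow_overrides(self, mesh: AxisymMesh, T_new, dTdt) -> dict:
        cpa = self.config.materials.cpa
        tris = mesh.cpa_tris
        m = tris.shape[0]
        if self.solid is None:
            self.solid = np.zeros(m, dtype=bool)
            self.stress = StressField.zeros(m)
        mu_unc = np.exp(np.log(np.atleast_1d(
            cpa.viscosity(T_new, cap=False))[tris]).mean(axis=1))
        self.solid |= mu_unc >= self.params.arrest_viscosity
        self.mu_unc = mu_unc
        if not self.solid.any():
            # nothing has arrested yet: take exactly the TF flow path
            return {}

        mu_eff = np.minimum(mu_unc, cpa.viscosity.mu_cap)
        mu_eff[self.solid] = np.minimum(mu_unc[self.solid],
                                        self.params.solid_viscosity_cap)

        rho = np.atleast_1d(cpa.density(T_new))
        drho = np.atleast_1d(cpa.density.derivative()(T_new))
        g_node = -(drho / rho) * dTdt
        g_elem = g_node[tris].mean(axis=1)
        dTdt_e = np.asarray(dTdt)[tris].mean(axis=1)
        g_elem[self.solid] = 3.0 * self.params.alpha * dTdt_e[self.solid]
        return {"viscosity_elem": mu_eff, "source_elem": g_elem}

    def snapshot_cell_data(self, mesh: AxisymMesh) -> dict:
        """Stress components on the full element list for VTU snapshots."""
        if self.stress is None:
            return {}
        m_total = mesh.tris.shape[0]
        cpa = np.nonzero(mesh.region == CPA)[0]
        out = {}
        for j, name in enumerate(("sigma_rr", "sigma_zz", "sigma_tt",
                                  "sigma_rz")):
            full = np.zeros(m_total)
            full[cpa] = self.stress.sigma[:, j]
            out[name] = full
        vm = np.zeros(m_total)
        vm[cpa] = self.stress.von_mises
        out["von_mises"] = vm
        solid = np.zeros(m_total)
        solid[cpa] = self.solid.astype(float)
        out["solid"] = solid
        return out

    # -- stress integration ---------------------------------------------
    def post_step(self, mesh: AxisymMesh, flowf, T_old, T_new, dt: float):
        tris = mesh.cpa_tris
        _, g = tri_geometry(mesh.nodes, tris)
        v = flowf.velocity[tris]                         # (M, 3, 2)
        L = np.einsum("mia,mib->mab", v, g)              # grad v per element
        deps = np.zeros((tris.shape[0], 4))
        deps[:, 0] = L[:, 0, 0] * dt                     # rr
        deps[:, 1] = L[:, 1, 1] * dt                     # zz
        deps[:, 3] = 0.5 * (L[:, 0, 1] + L[:, 1, 0]) * dt
        xq = np.einsum("qi,mij->mqj", QP, mesh.nodes[tris])
        r_mid = xq[..., 0].mean(axis=1)
        vr_mid = v[:, :, 0].mean(axis=1)
        deps[:, 2] = vr_mid / np.maximum(r_mid, 1e-300) * dt
        dT_e = (np.asarray(T_new) - np.asarray(T_old))[tris].mean(axis=1)

        mu = np.clip(self.mu_unc, 1e-12, self.params.solid_viscosity_cap)
        sig_new = update_stress(self.stress.sigma, deps, dT_e, dt, mu,
                                self.params)
        G = self.params.shear_modulus
        S_new = _dev(sig_new)
        self.stress.eps_creep += S_new / (2.0 * mu[:, None]) * dt
        self.stress.eps_thermal += np.multiply.outer(self.params.alpha * dT_e, _I)
        tr_new = sig_new[:, :3].sum(axis=1)
        self.stress.eps_elastic = (S_new / (2.0 * G)
                                   + np.multiply.outer(
                                       tr_new / (3.0 * self.params.bulk_factor), _I))
        self.stress.sigma = sig_new
        self.t += dt
        self.stress_history.append((self.t, float(self.stress.von_mises.max())))


def run_tm_simulation(config: SimulationConfig, params: MaxwellParameters
                      ) -> tuple[DisplacementHistory, _TMHooks]:
    """Run the TM model; returns the displacement history and stress state.

    The second element exposes ``stress`` (final :class:`StressField` on CPA
    elements), ``solid`` (arrested-element mask) and ``stress_history``
    ((t, max von Mises) per step).
    """
    hooks = _TMHooks(config, params)
    history = _run(config, tm_hooks=hooks)
    return history, hooks


def tf_tm_difference(h_tf: DisplacementHistory, h_tm: DisplacementHistory) -> float:
    """Relative TM-vs-TF difference of maximum displacement, percent."""
    ref = max_displacement(h_tf)
    if ref == 0:
        raise ValueError("TF displacement is zero; relative difference undefined")
    return abs(max_displacement(h_tm) - ref) / ref * 100.0
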