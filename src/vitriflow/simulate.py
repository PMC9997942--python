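"""Thermal-fluids (TF) simulation driver.

Orchestrates the cooling protocol and the per-step loop

    temperature step -> material derivative -> Stokes solve ->
    free-surface normal velocity -> ALE mesh motion

recording the centerline free-surface displacement history u_s(t) (signed,
negative = downward) together with diagnostics (surface volume flux, mesh
quality, viscosity range, CPA mass).  The pipeline is deterministic: no
randomness enters anywhere, and re-running an identical configuration
reproduces bit-identical outputs.

Time stepping is adaptive below a hard cap ``dt_max`` (default 20 s): the
step is shortened so the free surface never moves more than
``max_surface_step`` (default 0.3 mm, about 1% of the fill height) per
step, and halved on mesh-inversion retries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import thermal
from .geometry import (AxisymGeometry, AxisymMesh, RemeshRequired, build_mesh,
                       mesh_quality, move_free_surface, redistribute_columns)
from .materials import MaterialSet, default_materials

__all__ = ["ThermalProtocol", "SimulationConfig", "DisplacementHistory",
           "chamber_temperature", "run_tf_simulation", "max_displacement",
           "write_outputs"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermalProtocol:
    """Linear chamber cooling ramp with an optional terminal hold.

    ``cooling_rate`` is in degC/min (the convention cryopreservation
    protocols are quoted in); times are in seconds.
    """

    T_initial: float = 10.0
    cooling_rate: float = 20.0
    T_final: float = -125.0
    hold_duration: float = 0.0

    def __post_init__(self):
        # equality expresses a zero-forcing (isothermal hold) protocol
        if self.T_initial < self.T_final:
            raise ValueError("T_initial must not be below T_final")
        if self.cooling_rate <= 0:
            raise ValueError("cooling rate must be positive")
        if self.hold_duration < 0:
            raise ValueError("hold duration cannot be negative")

    @property
    def ramp_duration(self) -> float:
        return (self.T_initial - self.T_final) / self.cooling_rate * 60.0

    @property
    def total_duration(self) -> float:
        return self.ramp_duration + self.hold_duration


def chamber_temperature(protocol: ThermalProtocol, t: float) -> float:
    """Chamber temperature (degC) at time t (s) for the idealized ramp."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    T = protocol.T_initial - protocol.cooling_rate * t / 60.0
    T = np.maximum(T, protocol.T_final)
    return float(T) if T.ndim == 0 else T


@dataclass
class SimulationConfig:
    geometry: AxisymGeometry = field(default_factory=AxisymGeometry)
    materials: MaterialSet = field(default_factory=default_materials)
    protocol: ThermalProtocol = field(default_factory=ThermalProtocol)
    dt_max: float = 20.0              # s, hard cap on the time step
    dt_init: float = 5.0              # s, first step (no velocity known yet)
    target_elements: int = 4000
    max_surface_step: float = 3.0e-4  # m, surface-CFL cap per step
    gravity: float = 9.81
    arrest_threshold: float | None = None  # Pa.s; None = no flow exclusion
    remesh_quality: float = 0.1
    n_picard: int = 1
    picard_tol: float = 1.0e-3
    profile_every: int = 10           # surface-profile recording cadence
    snapshot_every: int = 0           # full-field VTU snapshot cadence (0=off)
    chamber_history: np.ndarray | None = None  # optional measured (t, T) table

    def __post_init__(self):
        if self.dt_max <= 0 or self.dt_init <= 0:
            raise ValueError("time steps must be positive")

    def chamber_temperature(self, t: float) -> float:
        if self.chamber_history is not None:
            tab = np.asarray(self.chamber_history, dtype=float)
            return float(np.interp(t, tab[:, 0], tab[:, 1]))
        return chamber_temperature(self.protocol, t)

    @property
    def duration(self) -> float:
        if self.chamber_history is not None:
            return float(np.asarray(self.chamber_history)[-1, 0])
        return self.protocol.total_duration


@dataclass
class DisplacementHistory:
    """Time series of the run plus surface-profile snapshots."""

    times: np.ndarray
    T_chamber: np.ndarray
    u_s: np.ndarray                   # m, signed (negative = downward)
    surface_flux: np.ndarray          # m^3/s through the free surface
    min_quality: np.ndarray
    max_mu_fluid: np.ndarray          # Pa.s, max element viscosity in flow
    cpa_mass: np.ndarray              # kg
    profiles: list = field(default_factory=list)   # (t, (r, z) array)
    snapshots: list = field(default_factory=list)  # (t, mesh, point_data)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.times,
            "T_chamber_C": self.T_chamber,
            "u_s_mm": self.u_s * 1e3,
            "surface_flux_m3_s": self.surface_flux,
            "min_mesh_quality": self.min_quality,
            "max_mu_fluid_Pa_s": self.max_mu_fluid,
            "cpa_mass_kg": self.cpa_mass,
        })


def max_displacement(history: DisplacementHistory) -> float:
    """Maximum |u_s| over the run, in mm."""
    if len(history.times) == 0:
        raise ValueError("empty displacement history")
    return float(np.max(np.abs(history.u_s)) * 1e3)


class _Recorder:
    def __init__(self):
        self.rows = []
        self.profiles = []
        self.snapshots = []

    def add(self, t, Tc, u_s, flux, quality, mu_max, mass):
        self.rows.append((t, Tc, u_s, flux, quality, mu_max, mass))

    def history(self) -> DisplacementHistory:
        arr = np.array(self.rows)
        return DisplacementHistory(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                                   arr[:, 4], arr[:, 5], arr[:, 6],
                                   self.profiles, self.snapshots)


def _surface_profile(mesh: AxisymMesh) -> np.ndarray:
    surf = mesh.free_surface_nodes
    return mesh.nodes[surf].copy()


def _run(config: SimulationConfig, tm_hooks=None) -> DisplacementHistory:
    """Shared TF / TM time loop.

    ``tm_hooks`` (see :mod:`vitriflow.maxwell`) may supply per-element
    viscosity and volume-source overrides and receive post-step strain
    updates; with ``tm_hooks=None`` this is the plain TF model.
    """
    mats = config.materials
    mesh = build_mesh(config.geometry, config.target_elements)
    n = mesh.nodes.shape[0]
    T = np.full(n, config.protocol.T_initial, dtype=float)
    v = np.zeros((n, 2))
    v_mesh = np.zeros((n, 2))
    t = 0.0
    t_end = config.duration
    z0 = mesh.nodes[mesh.free_surface_nodes[0], 1]
    mass0 = _cpa_mass(mesh, T, mats)

    rec = _Recorder()
    rec.add(0.0, config.chamber_temperature(0.0), 0.0, 0.0,
            mesh_quality(mesh), mats.cpa.viscosity(config.protocol.T_initial),
            mass0)
    rec.profiles.append((0.0, _surface_profile(mesh)))

    vn_max_prev = 0.0
    step = 0
    while t < t_end - 1e-9:
        dt = min(config.dt_max, t_end - t)
        if step == 0:
            dt = min(dt, config.dt_init)
        if vn_max_prev > 0:
            dt = min(dt, config.max_surface_step / vn_max_prev)
        for attempt in range(8):
            try:
                state = _advance(config, mesh, T, v, v_mesh, t, dt, tm_hooks)
                break
            except RemeshRequired:
                dt *= 0.5
                log.info("step %d: retrying with dt=%.3f s", step, dt)
        else:
            raise RuntimeError(
                f"unrecoverable mesh inversion at t={t:.1f} s (step {step})")
        mesh_new, T_new, flowf, vn, remeshed = state
        v_mesh = (mesh_new.nodes - mesh.nodes) / dt
        if tm_hooks is not None:
            tm_hooks.post_step(mesh, flowf, T, T_new, dt)
        mesh, T, v = mesh_new, T_new, flowf.velocity
        t += dt
        step += 1
        vn_max_prev = float(np.max(np.abs(vn))) if len(vn) else 0.0

        u_s = mesh.nodes[mesh.free_surface_nodes[0], 1] - z0
        rec.add(t, config.chamber_temperature(t), u_s,
                flow_mod.surface_flux(flowf, mesh),
                mesh_quality(mesh), flowf.info["mu_max"],
                _cpa_mass(mesh, T, mats))
        if config.profile_every and step % config.profile_every == 0:
            rec.profiles.append((t, _surface_profile(mesh)))
        if config.snapshot_every and step % config.snapshot_every == 0:
            point_data = {"T": T.copy(), "vr": flowf.vr.copy(),
                          "vz": flowf.vz.copy(), "p": flowf.p.copy()}
            cell_data = tm_hooks.snapshot_cell_data(mesh) \
                if tm_hooks is not None else None
            rec.snapshots.append((t, mesh.copy(), point_data, cell_data))
        if remeshed:
            log.info("step %d: column remesh (quality floor %.2f)",
                     step, config.remesh_quality)
    rec.profiles.append((t, _surface_profile(mesh)))
    hist = rec.history()
    drift = abs(hist.cpa_mass[-1] / mass0 - 1.0)
    log.info("run finished: %d steps, u_s(final) = %.3f mm, mass drift %.3f%%",
             step, hist.u_s[-1] * 1e3, 100 * drift)
    return hist


def _advance(config, mesh, T, v, v_mesh, t, dt, tm_hooks):
    """One loosely-coupled (optionally Picard-iterated) step."""
    mats = config.materials
    Tc = config.chamber_temperature(t + dt)
    v_iter = v
    vn_prev = None
    for it in range(max(1, config.n_picard)):
        T_new = thermal.step_temperature(mesh, T, v_iter - v_mesh, mats, Tc, dt)
        dTdt = thermal.material_derivative_T(mesh, T_new, T, v_iter, dt)
        overrides = {}
        if tm_hooks is not None:
            overrides = tm_hooks.flow_overrides(mesh, T_new, dTdt)
        flowf = flow_mod.solve_creeping_flow(
            mesh, T_new, dTdt, mats, config.gravity,
            arrest_threshold=config.arrest_threshold, surface_dt=dt,
            **overrides)
        vn = flow_mod.free_surface_normal_velocity(flowf, mesh)
        v_iter = flowf.velocity
        if vn_prev is not None:
            scale = max(np.max(np.abs(vn)), 1e-30)
            if np.max(np.abs(vn - vn_prev)) < config.picard_tol * scale:
                break
        vn_prev = vn

    mesh_new = move_free_surface(mesh, vn, dt)
    remeshed = False
    if mesh_quality(mesh_new) < config.remesh_quality:
        mesh_new, interp = redistribute_columns(mesh_new)
        T_new = interp(T_new)
        remeshed = True
    return mesh_new, T_new, flowf, vn, remeshed


def _cpa_mass(mesh: AxisymMesh, T: np.ndarray, mats: MaterialSet) -> float:
    from ._fem import QP, QW, quad_points, tri_geometry
    tris = mesh.cpa_tris
    area, _ = tri_geometry(mesh.nodes, tris)
    xq = quad_points(mesh.nodes, tris)
    rho_node = np.atleast_1d(mats.cpa.density(T))
    rho_q = np.einsum("qi,mi->mq", QP, rho_node[tris])
    return float(2 * np.pi * np.sum(area * ((rho_q * xq[..., 0]) * QW).sum(axis=1)))


def run_tf_simulation(config: SimulationConfig) -> DisplacementHistory:
    """Run the thermal-fluids (TF) model for the configured protocol."""
    return _run(config, tm_hooks=None)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def _config_dict(config: SimulationConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def write_outputs(history: DisplacementHistory, directory,
                  config: SimulationConfig | None = None) -> dict:
    """Write the CSV time series, VTU snapshot series and run metadata.

    Returns a dict of the paths written.  The CSV is bit-reproducible for
    identical configurations.
    """
    from .vtu import write_vtu_series

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        csv_path = directory / "history.csv"
        history.as_dataframe().to_csv(csv_path, index=False,
                                      float_format="%.10e")
        paths["history"] = str(csv_path)

        prof_rows = []
        for tprof, rz in history.profiles:
            for r, z in rz:
                prof_rows.append((tprof, r, z))
        prof_path = directory / "surface_profiles.csv"
        pd.DataFrame(prof_rows, columns=["t_s", "r_m", "z_m"]).to_csv(
            prof_path, index=False, float_format="%.10e")
        paths["profiles"] = str(prof_path)

        if history.snapshots:
            paths["vtu"] = write_vtu_series(history.snapshots, directory, "fields")

        if config is not None:
            meta_path = directory / "run_config.json"
            meta_path.write_text(json.dumps(_config_dict(config), indent=2))
            paths["config"] = str(meta_path)
        return paths
    except OSError as err:
        raise OSError(f"failed writing outputs under {directory}: {err}") from err
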