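"""YAML configuration loading for simulation runs.

Schema (all keys optional; defaults reproduce the reference cuvette study):

.. code-block:: yaml

    geometry:
      inner_radius: 5.0e-3        # m
      wall_thickness: 1.25e-3     # m
      height: 45.0e-3             # m
      fill_height: 27.5e-3        # m
    protocol:
      T_initial: 10.0             # degC
      cooling_rate: 20.0          # degC/min
      T_final: -125.0             # degC
      hold_duration: 0.0          # s
    materials:
      mu_ref: 1.0e-2              # Pa.s at T_ref
      T_ref: 10.0                 # degC
      mu_glass: 1.0e12            # Pa.s at T_glass
      T_glass: -132.0             # degC
      mu_cap: 1.0e8               # Pa.s numerical cap
      density_slope_factor: 1.0   # >1 steepens rho(T) (sensitivity study)
      cpa:                        # optional property overrides
        density: [1090.0, -0.6922, 0.000257]   # constant-first, kg/m^3
    numerics:
      dt_max: 20.0                # s
      target_elements: 4000
      max_surface_step: 3.0e-4    # m
      arrest_threshold: null      # Pa.s or null
    maxwell:
      E: 1.0e9                    # Pa
      nu: 0.33
      arrest_viscosity: 1.0e8     # Pa.s

Property polynomial coefficients are listed constant term first with
temperatures in degC and SI property units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .geometry import AxisymGeometry
from .materials import (MaterialSet, ViscosityModel, default_materials,
                        perturb_density_slope)
from .maxwell import MaxwellParameters
from .simulate import SimulationConfig, ThermalProtocol

__all__ = ["load_config", "load_maxwell_parameters"]


def _replace_poly(props, key, coeffs):
    poly = getattr(props, key)
    return dataclasses.replace(props, **{
        key: dataclasses.replace(poly, coefficients=tuple(coeffs))})


def _build_materials(section: dict) -> MaterialSet:
    mu_cap = float(section.get("mu_cap", 1.0e8))
    mats = default_materials(mu_cap=mu_cap)
    visc = ViscosityModel(
        mu_ref=float(section.get("mu_ref", 1.0e-2)),
        T_ref=float(section.get("T_ref", 10.0)),
        mu_glass=float(section.get("mu_glass", 1.0e12)),
        T_glass=float(section.get("T_glass", -132.0)),
        mu_cap=mu_cap)
    cpa = dataclasses.replace(mats.cpa, viscosity=visc)
    for key in ("density", "conductivity", "specific_heat"):
        if key in section.get("cpa", {}):
            cpa = _replace_poly(cpa, key, section["cpa"][key])
    factor = float(section.get("density_slope_factor", 1.0))
    if factor != 1.0:
        cpa = dataclasses.replace(
            cpa, density=perturb_density_slope(cpa.density, factor))
    cuvette = mats.cuvette
    for key in ("density", "conductivity", "specific_heat"):
        if key in section.get("cuvette", {}):
            cuvette = _replace_poly(cuvette, key, section["cuvette"][key])
    return dataclasses.replace(mats, cpa=cpa, cuvette=cuvette,
                               h_free=float(section.get("h_free", 10.0)),
                               h_forced=float(section.get("h_forced", 350.0)))


def load_config(path=None, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file plus overrides.

    ``overrides`` accepts the flat keys ``cooling_rate``, ``T_final``,
    ``target_elements``, ``dt_max`` (CLI conveniences).
    """
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}

    geometry = AxisymGeometry(**{k: float(v) for k, v in
                                 (data.get("geometry") or {}).items()})
    prot = dict(data.get("protocol") or {})
    for key in ("cooling_rate", "T_final", "T_initial", "hold_duration"):
        if key in overrides and overrides[key] is not None:
            prot[key] = overrides[key]
    protocol = ThermalProtocol(**{k: float(v) for k, v in prot.items()})
    materials = _build_materials(dict(data.get("materials") or {}))

    num = dict(data.get("numerics") or {})
    for key in ("target_elements", "dt_max", "max_surface_step",
                "arrest_threshold", "snapshot_every"):
        if key in overrides and overrides[key] is not None:
            num[key] = overrides[key]
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    int_keys = {"target_elements", "n_picard", "profile_every", "snapshot_every"}
    kwargs = {}
    for key, val in num.items():
        if key not in valid:
            raise ValueError(f"unknown numerics option: {key}")
        if val is None:
            kwargs[key] = None
        else:
            kwargs[key] = int(val) if key in int_keys else float(val)
    return SimulationConfig(geometry=geometry, materials=materials,
                            protocol=protocol, **kwargs)


def load_maxwell_parameters(path=None) -> MaxwellParameters:
    data = {}
    if path is not None:
        data = (yaml.safe_load(Path(path).read_text()) or {}).get("maxwell") or {}
    return MaxwellParameters(**{k: float(v) for k, v in data.items()})
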