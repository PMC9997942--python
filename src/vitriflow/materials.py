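"""Temperature-dependent thermophysical property models.

Property fits for 7.05M DMSO (the cryoprotective agent, CPA) and the
polystyrene cuvette are low-order polynomials in temperature (degrees
Celsius).  The dynamic viscosity of the vitrifying CPA is modelled with a
single exponential term spanning roughly fourteen orders of magnitude
between the initial temperature and the glass transition of 7.05M DMSO
(about -132 C); the two anchor points (reference and glass-transition
viscosity) are configuration parameters because measured values for this
solution are only sparsely available in the literature.

All temperatures are in degrees Celsius; properties are in SI units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PropertyPolynomial",
    "ViscosityModel",
    "MaterialProperties",
    "MaterialSet",
    "evaluate_property",
    "viscosity",
    "calibrate_viscosity",
    "perturb_density_slope",
    "default_materials",
]

log = logging.getLogger(__name__)


class PropertyRangeError(ValueError):
    """Temperature outside a property fit's valid range with clamping off."""


@dataclass(frozen=True)
class PropertyPolynomial:
    """Polynomial property fit, constant term first, T in degrees Celsius."""

    coefficients: tuple
    units: str = ""
    name: str = "property"
    valid_range: tuple = (-140.0, 30.0)
    clamp: bool = True

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"invalid temperature range for {self.name}: {self.valid_range}")

    def __call__(self, T):
        return evaluate_property(self, T)

    def derivative(self):
        """Polynomial d(property)/dT as a new PropertyPolynomial."""
        c = self.coefficients
        dc = tuple(i * c[i] for i in range(1, len(c))) or (0.0,)
        return replace(self, coefficients=dc, name=f"d({self.name})/dT",
                       units=f"{self.units}/degC")


def evaluate_property(poly: PropertyPolynomial, T):
    """Evaluate ``sum_i c_i T^i`` at temperature(s) ``T`` (degC).

    Out-of-range temperatures are clamped to the fit interval with a log
    entry when ``poly.clamp`` is set, and raise :class:`PropertyRangeError`
    otherwise (silent extrapolation is never performed).
    """
    T = np.asarray(T, dtype=float)
    lo, hi = poly.valid_range
    out = (T < lo) | (T > hi)
    if np.any(out):
        if not poly.clamp:
            bad = float(np.asarray(T)[out].flat[0])
            raise PropertyRangeError(
                f"{poly.name}: T={bad:g} degC outside valid range [{lo:g}, {hi:g}]")
        log.warning("%s: clamping %d temperature(s) to [%g, %g] degC",
                    poly.name, int(np.count_nonzero(out)), lo, hi)
        T = np.clip(T, lo, hi)
    val = np.polynomial.polynomial.polyval(T, poly.coefficients)
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class ViscosityModel:
    """Single-exponential viscosity law ``mu(T) = mu_ref * exp(b (T_ref - T))``.

    ``b`` is derived from two anchors, the reference viscosity ``mu_ref`` at
    ``T_ref`` and the glass-transition viscosity ``mu_glass`` at ``T_glass``.
    ``mu_cap`` is a purely numerical ceiling keeping the Stokes system
    conditioned; capping is logged when active.
    """

    mu_ref: float = 1.0e-2
    T_ref: float = 10.0
    mu_glass: float = 1.0e12
    T_glass: float = -132.0
    mu_cap: float = 1.0e8

    def __post_init__(self):
        if not (self.T_ref > self.T_glass):
            raise ValueError("T_ref must exceed T_glass")
        if not (self.mu_glass > self.mu_ref > 0.0):
            raise ValueError("anchors must satisfy mu_glass > mu_ref > 0")
        if self.mu_cap <= 0:
            raise ValueError("mu_cap must be positive")

    @property
    def b(self) -> float:
        """Exponential slope, 1/degC (positive: mu grows on cooling)."""
        return math.log(self.mu_glass / self.mu_ref) / (self.T_ref - self.T_glass)

    def __call__(self, T, cap: bool = True):
        return viscosity(self, T, cap=cap)


def calibrate_viscosity(mu_ref: float, T_ref: float, mu_glass: float,
                        T_glass: float, mu_cap: float = 1.0e8) -> ViscosityModel:
    """Build a :class:`ViscosityModel` from two (mu, T) anchor points."""
    return ViscosityModel(mu_ref=mu_ref, T_ref=T_ref, mu_glass=mu_glass,
                          T_glass=T_glass, mu_cap=mu_cap)


def viscosity(model: ViscosityModel, T, cap: bool = True):
    """Dynamic viscosity in Pa.s at temperature(s) ``T`` (degC)."""
    b = model.b  # raises if the dataclass was built uncalibrated
    T = np.asarray(T, dtype=float)
    # evaluate in log space to avoid overflow deep below Tg
    log_mu = math.log(model.mu_ref) + b * (model.T_ref - T)
    mu = np.exp(log_mu)
    if cap:
        n_capped = int(np.count_nonzero(mu > model.mu_cap))
        if n_capped:
            log.debug("viscosity cap %g Pa.s active at %d point(s)",
                      model.mu_cap, n_capped)
        mu = np.minimum(mu, model.mu_cap)
    return float(mu) if mu.ndim == 0 else mu


def perturb_density_slope(poly: PropertyPolynomial, factor: float) -> PropertyPolynomial:
    """Steepen (or flatten) a density fit's temperature dependence.

    All non-constant coefficients are scaled by ``factor`` so that the value
    at 0 degC is preserved; used for the hypothetical-CPA sensitivity study
    (e.g. a density slope 15% steeper than 7.05M DMSO).
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    c = poly.coefficients
    new = (c[0],) + tuple(factor * ci for ci in c[1:])
    return replace(poly, coefficients=new, name=f"{poly.name} (slope x{factor:g})")


@dataclass(frozen=True)
class MaterialProperties:
    """Property bundle for one material."""

    density: PropertyPolynomial
    conductivity: PropertyPolynomial
    specific_heat: PropertyPolynomial
    thermal_expansion: float
    viscosity: ViscosityModel | None = None


@dataclass(frozen=True)
class MaterialSet:
    """CPA + cuvette properties and chamber heat transfer coefficients.

    ``h_free`` applies where a surface exchanges with still air (CPA free
    surface, exposed wall surfaces above the fill line); ``h_forced`` applies
    on the outer cuvette surface swept by the chamber coolant stream.
    """

    cpa: MaterialProperties
    cuvette: MaterialProperties
    h_free: float = 10.0     # W/m^2-degC
    h_forced: float = 350.0  # W/m^2-degC

    def __post_init__(self):
        if self.h_free <= 0 or self.h_forced <= 0:
            raise ValueError("heat transfer coefficients must be positive")
        if self.cpa.viscosity is None:
            raise ValueError("CPA material requires a viscosity model")

    def for_region(self, region_name: str) -> MaterialProperties:
        if region_name == "cpa":
            return self.cpa
        if region_name in ("wall", "cuvette"):
            return self.cuvette
        raise KeyError(region_name)


def default_materials(mu_cap: float = 1.0e8,
                      valid_range: tuple = (-140.0, 30.0),
                      clamp: bool = True) -> MaterialSet:
    """Property set for 7.05M DMSO in a polystyrene cuvette.

    Density, conductivity and specific heat are published polynomial fits in
    degC; thermal expansion coefficients are constants (used only by the
    solid-mechanics stress model — in the thermal-fluids model volumetric
    change enters exclusively through rho(T)).
    """
    def P(name, units, *coeffs):
        return PropertyPolynomial(coefficients=coeffs, units=units, name=name,
                                  valid_range=valid_range, clamp=clamp)

    cpa = MaterialProperties(
        density=P("CPA density", "kg/m^3", 1090.0, -0.6922, 0.000257),
        conductivity=P("CPA conductivity", "W/m-degC",
                       0.356, 7.42e-4, -1.29e-6, -6.87e-8, -2.95e-10),
        specific_heat=P("CPA specific heat", "J/kg-degC",
                        2804.0, 4.205, -0.054, -4.902e-5),
        thermal_expansion=1.1e-5,
        viscosity=ViscosityModel(mu_cap=mu_cap),
    )
    cuvette = MaterialProperties(
        density=P("cuvette density", "kg/m^3", 1055.0, -0.26),
        conductivity=P("cuvette conductivity", "W/m-degC", 0.14, 1.3e-4),
        specific_heat=P("cuvette specific heat", "J/kg-degC", 1121.0, 3.94),
        thermal_expansion=8.0e-5,
    )
    return MaterialSet(cpa=cpa, cuvette=cuvette)
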