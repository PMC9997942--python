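"""Analytic oracles and synthetic-data generators for verification.

Everything here is computable without external data: a transient
Robin-cooled slab series solution (conduction benchmark), the
uniform-contraction closed form for the free-surface displacement
(mass-balance limit of slow cooling), and a synthetic cryomacroscopy frame
generator that inverts the screen-scaling reduction exactly.  All
generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import AxisymGeometry
from .macroscopy import FrameMeasurement
from .materials import PropertyPolynomial

__all__ = ["SlabBenchmark", "slab_robin_temperature",
           "uniform_contraction_displacement", "generate_synthetic_frames"]


@dataclass(frozen=True)
class SlabBenchmark:
    """Symmetrically Robin-cooled slab, constant properties.

    ``half_thickness`` is L in the classic one-term-series geometry: the
    slab occupies |x| <= L, starts uniformly at ``T_initial`` and exchanges
    with a constant ambient ``T_ambient`` through film coefficient h on
    both faces.
    """

    half_thickness: float = 5.0e-3     # m
    conductivity: float = 0.356        # W/m-degC
    density: float = 1090.0            # kg/m^3
    specific_heat: float = 2804.0      # J/kg-degC
    h: float = 71.2                    # W/m^2-degC
    T_initial: float = 10.0            # degC
    T_ambient: float = -60.0           # degC
    n_terms: int = 50

    def __post_init__(self):
        if self.biot <= 0 or not np.isfinite(self.biot):
            raise ValueError("Biot number must be finite and positive")
        if self.n_terms < 20:
            raise ValueError("series truncation must keep at least 20 terms")

    @property
    def diffusivity(self) -> float:
        return self.conductivity / (self.density * self.specific_heat)

    @property
    def biot(self) -> float:
        return self.h * self.half_thickness / self.conductivity


def _slab_eigenvalues(bi: float, n: int) -> np.ndarray:
    """Roots of lambda tan(lambda) = Bi, one per interval ((k-1)pi, (k-1/2)pi)."""
    roots = []
    f = lambda lam: lam * np.tan(lam) - bi
    for k in range(n):
        lo = k * np.pi + 1e-9
        hi = k * np.pi + np.pi / 2 - 1e-9
        try:
            roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
        except ValueError as err:  # pragma: no cover
            raise RuntimeError(f"eigenvalue search failed in mode {k}") from err
    return np.array(roots)


def slab_robin_temperature(benchmark: SlabBenchmark, x, t) -> np.ndarray:
    """Series solution T(x, t) of the Robin-cooled slab (degC).

    theta/theta_i = sum_n C_n exp(-lam_n^2 Fo) cos(lam_n x/L) with
    lam_n tan lam_n = Bi and C_n = 4 sin lam_n / (2 lam_n + sin 2 lam_n).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0) or np.any(x > benchmark.half_thickness):
        raise ValueError("x must lie in [0, half_thickness]")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam = _slab_eigenvalues(benchmark.biot, benchmark.n_terms)
    C = 4.0 * np.sin(lam) / (2.0 * lam + np.sin(2.0 * lam))
    L = benchmark.half_thickness
    fo = benchmark.diffusivity * t / L**2
    theta = _series_eval(C, lam, x / L, fo)
    out = benchmark.T_ambient + (benchmark.T_initial - benchmark.T_ambient) * theta
    return out if out.size > 1 else float(out.flat[0])


def _series_eval(C, lam, xi, fo):
    xi = np.atleast_1d(xi)
    fo = np.atleast_1d(fo)
    decay = np.exp(-np.multiply.outer(fo, lam**2))        # (T, n)
    shape = np.cos(np.multiply.outer(xi, lam))            # (X, n)
    theta = np.einsum("tn,xn,n->tx", decay, shape, C)
    return np.squeeze(theta)


def uniform_contraction_displacement(geometry: AxisymGeometry,
                                     density: PropertyPolynomial,
                                     T0: float, T1: float) -> float:
    """Closed-form surface displacement for uniform cooling, in mm.

    Rigid walls and a spatially uniform temperature: mass conservation
    rho(T0) h0 = rho(T1) h1 gives u_s = h0 (rho(T0)/rho(T1) - 1), negative
    when the CPA densifies on cooling.
    """
    r0 = density(T0)
    r1 = density(T1)
    return float(geometry.fill_height * (r0 / r1 - 1.0) * 1e3)


def generate_synthetic_frames(true_displacement_series, scale_px_per_mm: float,
                              noise_sd: float, seed: int, *,
                              Le: float = 10.0, He0: float = 2.0,
                              times=None) -> list:
    """Frames whose noiseless reduction reproduces a displacement series.

    The physical cavity height is H_e(t) = He0 + u_s(t); on-screen lengths
    are the physical ones times ``scale_px_per_mm`` (the screen "mm" of the
    measurement tool), with i.i.d. Gaussian noise of ``noise_sd`` (screen
    mm) added to H_p and both apparent widths when ``noise_sd > 0``.
    Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    us = np.asarray(true_displacement_series, dtype=float)
    rng = np.random.default_rng(seed)
    he = He0 + us
    if np.any(he <= 0):
        raise ValueError("He0 too small: cavity height must stay positive")
    t = np.arange(len(us), dtype=float) if times is None else np.asarray(times)
    frames = []
    for i, h in enumerate(he):
        hp = scale_px_per_mm * h
        lpf = scale_px_per_mm * Le
        lpb = scale_px_per_mm * Le
        if noise_sd > 0:
            hp += rng.normal(0.0, noise_sd)
            lpf += rng.normal(0.0, noise_sd)
            lpb += rng.normal(0.0, noise_sd)
        frames.append(FrameMeasurement(Hp=hp, Lp_front=lpf, Lp_back=lpb,
                                       Le=Le, time=float(t[i])))
    return frames
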