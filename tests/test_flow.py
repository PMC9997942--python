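import dataclasses

import numpy as np
import pytest

from vitriflow.flow import (FlowField, free_surface_normal_velocity,
                            solve_creeping_flow, surface_flux,
                            surface_traction_residual)
from vitriflow.geometry import (AxisymGeometry, build_box_mesh, build_mesh)
from vitriflow.materials import ViscosityModel

GEO = AxisymGeometry()


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(GEO, 1500)


def test_hydrostatic_equilibrium(mesh, mats):
    n = len(mesh.nodes)
    T = np.full(n, 10.0)
    f = solve_creeping_flow(mesh, T, np.zeros(n), mats)
    assert np.abs(f.velocity).max() < 1e-10
    rho = mats.cpa.density(10.0)
    p_exact = rho * 9.81 * (GEO.fill_height - mesh.nodes[:, 1])
    assert f.p[f.in_cpa] == pytest.approx(p_exact[f.in_cpa], abs=1e-8)


def test_uniform_contraction_mass_balance(mesh, mats):
    # spatially uniform cooling rate: the outflow through the free surface
    # must equal the volumetric contraction source to < 1%
    n = len(mesh.nodes)
    T = np.full(n, 10.0)
    rate = 20.0 / 60.0
    f = solve_creeping_flow(mesh, T, np.full(n, -rate), mats)
    rho = mats.cpa.density(10.0)
    drho = mats.cpa.density.derivative()(10.0)
    volume = np.pi * GEO.inner_radius**2 * GEO.fill_height
    expected = volume * (drho / rho) * rate  # negative: contraction
    assert surface_flux(f, mesh) == pytest.approx(expected, rel=0.01)


def test_viscosity_scaling_invariance(mesh, mats):
    # with gravity off and only the contraction source driving flow, the
    # Stokes solution is invariant to a global viscosity rescaling
    n = len(mesh.nodes)
    T = 10.0 - 40.0 * (mesh.nodes[:, 0] / GEO.outer_radius)  # radial gradient
    dTdt = np.full(n, -0.3)
    f1 = solve_creeping_flow(mesh, T, dTdt, mats, gravity=0.0)
    visc = mats.cpa.viscosity
    scaled = ViscosityModel(mu_ref=100 * visc.mu_ref, T_ref=visc.T_ref,
                            mu_glass=100 * visc.mu_glass, T_glass=visc.T_glass,
                            mu_cap=100 * visc.mu_cap)
    mats2 = dataclasses.replace(
        mats, cpa=dataclasses.replace(mats.cpa, viscosity=scaled))
    f2 = solve_creeping_flow(mesh, T, dTdt, mats2, gravity=0.0)
    scale = np.abs(f1.velocity).max()
    assert np.abs(f2.velocity - f1.velocity).max() < 1e-6 * scale


def test_normal_velocity_trivial_cases(mesh, mats):
    n = len(mesh.nodes)
    zero = FlowField(np.zeros(n), np.zeros(n), np.zeros(n),
                     np.ones(n, dtype=bool))
    assert np.all(free_surface_normal_velocity(zero, mesh) == 0.0)
    w = 1e-4
    down = FlowField(np.zeros(n), np.full(n, -w), np.zeros(n),
                     np.ones(n, dtype=bool))
    vn = free_surface_normal_velocity(down, mesh)
    assert vn[:-1] == pytest.approx(-w, rel=1e-12)   # flat surface: n = +z
    assert vn[-1] == 0.0                             # contact node forced


def test_normal_velocity_on_tilted_surface():
    # surface tilted at 45 degrees: uniform (0, -w) has v.n = -w/sqrt(2)
    mesh = build_box_mesh(1.0, 2.0, 4, 4)
    surf = mesh.free_surface_nodes
    nodes = mesh.nodes.copy()
    nodes[surf, 1] += nodes[surf, 0]                 # slope dz/dr = 1
    mesh.nodes = nodes
    n = len(mesh.nodes)
    w = 2.0
    flow = FlowField(np.zeros(n), np.full(n, -w), np.zeros(n),
                     np.ones(n, dtype=bool))
    vn = free_surface_normal_velocity(flow, mesh)
    assert vn[1:-1] == pytest.approx(-w / np.sqrt(2.0), rel=1e-12)


def test_mirror_symmetry_planar(mats):
    # reflecting the temperature field about the mid-plane of a slab reflects
    # the velocity solution (no-slip side walls, free top, planar geometry)
    mesh = build_box_mesh(1e-2, 1e-2, 12, 12)
    x = mesh.nodes[:, 0]
    T = 10.0 - 3.0e3 * x                              # asymmetric gradient
    dTdt = np.full(len(x), -0.3)
    kw = dict(axisymmetric=False, gravity=0.0,
              noslip_tags=("left", "right", "bottom"), axis_tag="none")
    f1 = solve_creeping_flow(mesh, T, dTdt, mats, **kw)
    T_ref = 10.0 - 3.0e3 * (1e-2 - x)                 # mirrored field
    f2 = solve_creeping_flow(mesh, T_ref, dTdt, mats, **kw)
    # mirror map on the structured grid: node (i, j) -> (nx - i, j)
    grid = mesh.structure["cpa_grid"]
    mirror = np.empty(len(x), dtype=int)
    mirror[grid.ravel()] = grid[::-1, :].ravel()
    scale = np.abs(f1.velocity).max()
    assert scale > 0
    assert np.abs(f2.vr + f1.vr[mirror]).max() < 1e-10 * scale
    assert np.abs(f2.vz - f1.vz[mirror]).max() < 1e-10 * scale


def test_traction_residual_behaviour(mats):
    n_coarse = build_mesh(GEO, 500)
    n_fine = build_mesh(GEO, 8000)
    vals = {}
    for label, m in (("coarse", n_coarse), ("fine", n_fine)):
        nn = len(m.nodes)
        T = np.full(nn, -60.0)
        f = solve_creeping_flow(m, T, np.full(nn, -1 / 3), mats, gravity=0.0)
        vals[label] = surface_traction_residual(
            f, m, T, mats, exclude_radius_fraction=0.7)
        assert np.isfinite(vals[label])
    # residual shrinks under refinement away from the contact-corner
    # singularity
    assert vals["fine"] < 0.6 * vals["coarse"]
    # hydrostatic case: traction-free surface satisfied to solver tolerance
    nn = len(n_coarse.nodes)
    T = np.full(nn, 10.0)
    f0 = solve_creeping_flow(n_coarse, T, np.zeros(nn), mats)
    assert surface_traction_residual(f0, n_coarse, T, mats) < 1e-8
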