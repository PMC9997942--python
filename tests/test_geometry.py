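import numpy as np
import pytest

from vitriflow._fem import tri_geometry
from vitriflow.geometry import (CPA, AxisymGeometry, AxisymMesh, build_mesh,
                                cpa_volume, element_quality, mesh_quality,
                                move_free_surface, redistribute_columns,
                                surface_normals)

GEO = AxisymGeometry()


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(GEO, 2000)


def test_build_mesh_geometry_and_tags(mesh):
    area, _ = tri_geometry(mesh.nodes, mesh.tris)
    assert np.all(area > 0)
    cpa_area = area[mesh.region == CPA].sum()
    assert cpa_area == pytest.approx(GEO.inner_radius * GEO.fill_height, rel=1e-12)
    assert abs(len(mesh.tris) - 2000) <= 0.25 * 2000
    assert mesh_quality(mesh) > 0.2
    axis_nodes = mesh.nodes_of("axis")
    assert np.all(mesh.nodes[axis_nodes, 0] == 0.0)
    for tag in ("axis", "outer_surface", "free_surface", "wall_cpa_interface",
                "cpa_bottom_interface", "wall_top"):
        assert len(mesh.edges[tag]) > 0
    # surface node ordering: axis first, wall contact last
    surf = mesh.free_surface_nodes
    assert mesh.nodes[surf[0], 0] == 0.0
    assert mesh.nodes[surf[-1], 0] == pytest.approx(GEO.inner_radius)
    assert cpa_volume(mesh) == pytest.approx(
        np.pi * GEO.inner_radius**2 * GEO.fill_height, rel=1e-12)


def test_build_mesh_rejects_bad_input():
    with pytest.raises(ValueError):
        AxisymGeometry(fill_height=0.0)
    with pytest.raises(ValueError):
        AxisymGeometry(fill_height=50e-3)  # above the container height
    with pytest.raises(ValueError):
        build_mesh(GEO, 50)


def _single_triangle(points):
    return AxisymMesh(np.asarray(points, dtype=float), np.array([[0, 1, 2]]),
                      np.array([0], dtype=np.int8))


@pytest.mark.parametrize("points,expected", [
    ([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)], 1.0),        # equilateral
    ([(0, 0), (4, 0), (4, 3)], 0.8),                        # 3-4-5 right
    ([(0, 0), (1, 0), (2, 0)], 0.0),                        # degenerate
])
def test_quality_metric_reference_values(points, expected):
    # metric: q = 2 r_in / r_circ = 16 A^2 / (perimeter * a * b * c)
    q = element_quality(_single_triangle(points))[0]
    assert q == pytest.approx(expected, abs=1e-12)


def test_move_free_surface_zero_velocity_identity(mesh):
    vn = np.zeros(len(mesh.free_surface_nodes))
    out = move_free_surface(mesh, vn, 10.0)
    assert np.array_equal(out.nodes, mesh.nodes)


def test_move_free_surface_uniform_descent(mesh):
    w = 1e-5
    dt = 5.0
    vn = np.full(len(mesh.free_surface_nodes), -w)
    out = move_free_surface(mesh, vn, dt)
    surf = out.free_surface_nodes
    z = out.nodes[surf, 1]
    # interior surface nodes all drop by w dt; pinned contact stays
    assert z[:-1] == pytest.approx(GEO.fill_height - w * dt, rel=1e-9)
    assert out.nodes[surf[-1], 1] == pytest.approx(GEO.fill_height)
    # wall nodes never move
    wall_nodes = np.setdiff1d(np.arange(len(mesh.nodes)), np.unique(mesh.cpa_tris))
    assert np.array_equal(out.nodes[wall_nodes], mesh.nodes[wall_nodes])
    assert np.all(out.nodes[out.nodes_of("axis"), 0] == 0.0)


def test_move_free_surface_quality_retention(mesh):
    rng = np.random.default_rng(42)
    q0 = mesh_quality(mesh)
    r = mesh.nodes[mesh.free_surface_nodes, 0] / GEO.inner_radius
    for _ in range(6):
        # smooth random dome motion with displacement <= 5% of fill height
        a = rng.uniform(-0.05, 0.05)
        vn = a * GEO.fill_height * (1 - r**2)
        out = move_free_surface(mesh, vn, 1.0)
        assert mesh_quality(out) >= 0.5 * q0


def test_volume_change_matches_surface_flux(mesh):
    # rigid downward translation is divergence-free: volume change must equal
    # the surface flux integral (discrete divergence theorem)
    w, dt = 2e-5, 5.0
    surf = mesh.free_surface_nodes
    normals = surface_normals(mesh)
    vn = -w * normals[:, 1]
    vn[-1] = 0.0                 # contact node pinned by the mover as well
    out = move_free_surface(mesh, vn, dt)
    dv = cpa_volume(out) - cpa_volume(mesh)
    vn_of = dict(zip(surf.tolist(), vn))
    flux = 0.0
    for e0, e1 in mesh.edges["free_surface"]:
        p0, p1 = mesh.nodes[e0], mesh.nodes[e1]
        length = np.hypot(*(p1 - p0))
        for s, wq in ((0.5 - 0.5 / np.sqrt(3), 0.5),
                      (0.5 + 0.5 / np.sqrt(3), 0.5)):
            r_q = (1 - s) * p0[0] + s * p1[0]
            vn_q = (1 - s) * vn_of[e0] + s * vn_of[e1]
            flux += wq * 2 * np.pi * r_q * length * vn_q
    assert dv == pytest.approx(flux * dt, rel=0.01)


def test_redistribute_columns_preserves_shape_and_fields(mesh):
    rng = np.random.default_rng(7)
    vn = -np.abs(rng.normal(1e-5, 5e-6, len(mesh.free_surface_nodes)))
    moved = move_free_surface(mesh, vn, 10.0)
    fixed, interp = redistribute_columns(moved)
    assert fixed.tris is moved.tris and fixed.edges is moved.edges
    assert np.all(fixed.element_areas() > 0)
    assert cpa_volume(fixed) == pytest.approx(cpa_volume(moved), rel=2e-3)
    # wall untouched
    wall_nodes = np.setdiff1d(np.arange(len(mesh.nodes)), np.unique(mesh.cpa_tris))
    assert np.allclose(fixed.nodes[wall_nodes], mesh.nodes[wall_nodes])
    # linear-in-z nodal field re-interpolates exactly along columns
    field = 3.0 * moved.nodes[:, 1] + 1.0
    expect = 3.0 * fixed.nodes[:, 1] + 1.0
    got = interp(field)
    cpa_nodes = np.unique(mesh.cpa_tris)
    assert got[cpa_nodes] == pytest.approx(expect[cpa_nodes], abs=1e-9)
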