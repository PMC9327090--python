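import numpy as np
import pytest
import trimesh

from thoraco import (GeometrySummary, TriangleMesh, add_closure_markers,
                     level_diameters, mesh_surface_area, mesh_volume,
                     plane_section, shape_factors, trunk_height,
                     volume_error, volume_trace_l)
from thoraco.geometry import GeometryError
from conftest import rigid_transform


def _cube(size=100.0):
    tm = trimesh.creation.box(extents=(size, size, size))
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def _sphere(r=80.0, subdivisions=4):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def test_cube_volume_area_exact():
    cube = _cube(100.0)
    assert mesh_volume(cube) == pytest.approx(1.0, rel=1e-12)       # 1 L
    assert mesh_surface_area(cube) == pytest.approx(6.0, rel=1e-12)  # 6 dm^2


def test_tetrahedron_volume_exact():
    v = np.array([[0, 0, 0], [60, 0, 0], [0, 60, 0], [0, 0, 60]], float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    m = TriangleMesh(v, f)
    m.ensure_outward()
    assert mesh_volume(m) == pytest.approx(60**3 / 6 * 1e-6, rel=1e-12)


def test_sphere_volume_converges():
    sph = _sphere(80.0, subdivisions=5)
    exact = 4.0 / 3.0 * np.pi * 80.0**3 * 1e-6
    assert mesh_volume(sph) == pytest.approx(exact, rel=2e-3)
    assert mesh_surface_area(sph) == pytest.approx(
        4.0 * np.pi * 80.0**2 * 1e-4, rel=2e-3)


def test_volume_rigid_invariant(trunk0):
    r, t = rigid_transform(3)
    moved = trunk0.transformed(rotation=r, translation=t)
    assert mesh_volume(moved) == pytest.approx(mesh_volume(trunk0), rel=1e-10)
    assert mesh_surface_area(moved) == pytest.approx(
        mesh_surface_area(trunk0), rel=1e-10)


def test_volume_scale_covariant(trunk0):
    scaled = trunk0.transformed(scale=2.0)
    assert mesh_volume(scaled) == pytest.approx(8 * mesh_volume(trunk0), rel=1e-12)
    assert mesh_surface_area(scaled) == pytest.approx(
        4 * mesh_surface_area(trunk0), rel=1e-12)


def test_open_mesh_volume_rejected(trunk0):
    open_mesh = TriangleMesh(trunk0.vertices.copy(), trunk0.faces[:-1].copy())
    with pytest.raises(GeometryError):
        mesh_volume(open_mesh)


def test_cube_section_exact():
    cube = _cube(100.0)
    sect = plane_section(cube, 10.0)
    assert sect.area_dm2 == pytest.approx(1.0, rel=1e-9)       # 1 dm^2
    assert sect.perimeter_cm == pytest.approx(40.0, rel=1e-9)  # 40 cm


def test_sphere_section_circle():
    sph = _sphere(80.0, subdivisions=5)
    z = 30.0
    r = np.sqrt(80.0**2 - z**2)
    sect = plane_section(sph, z)
    assert sect.area_dm2 == pytest.approx(np.pi * r**2 * 1e-4, rel=5e-3)
    assert sect.perimeter_cm == pytest.approx(2 * np.pi * r * 0.1, rel=5e-3)


def test_section_through_vertex_plane_nudged():
    # cut a double pyramid exactly at a vertex height
    v = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0], [30, 30, 50],
                  [10, 10, -50]], float)
    f = np.array([[0, 1, 3], [1, 2, 3], [2, 0, 3],
                  [1, 0, 4], [2, 1, 4], [0, 2, 4]])
    m = TriangleMesh(v, f)
    m.ensure_outward()
    sect = plane_section(m, 0.0)  # plane contains 3 vertices
    assert sect.area_dm2 > 0


def test_section_outside_extent_rejected(trunk0):
    with pytest.raises(GeometryError):
        plane_section(trunk0, 1e5)


def test_level_diameters_synthetic(layout, clean_session):
    cfg, trajs, _ = clean_session
    frame = trajs.frame(0)
    for level, row in layout.level_rows.items():
        d = level_diameters(frame, layout, level)
        # noise-free phantom at s(0)=0: AP = 2*b0, ML = 2*a0 of the row
        assert d["ML"] == pytest.approx(2 * cfg.a0_mm[row - 1] * 0.1, rel=1e-9)
        assert d["AP"] == pytest.approx(2 * cfg.b0_mm[row - 1] * 0.1, rel=1e-9)


def test_trunk_height_phantom(layout, clean_session):
    cfg, trajs, _ = clean_session
    closed = add_closure_markers(trajs.frame(0), layout, "trunk")
    assert trunk_height(closed) == pytest.approx(cfg.height_mm * 0.1, rel=1e-9)


def test_summary_cw_sum_and_percentages():
    s = GeometrySummary(
        phase="FRC", trunk_height_cm=50.0,
        diameters_cm={lv: {"AP": 20.0, "ML": 28.0}
                      for lv in ("louis_angle", "xiphoid", "umbilicus")},
        perimeters_cm={lv: 90.0 for lv in ("louis_angle", "xiphoid", "umbilicus")},
        areas_dm2={lv: 6.0 for lv in ("louis_angle", "xiphoid", "umbilicus")},
        surface_area_dm2=40.0,
        volumes_l={"RCp": 10.0, "RCa": 3.0, "AB": 7.0, "CW_obj": 21.0},
    )
    assert s.volumes_l["CW_sum"] == pytest.approx(20.0)
    pct = s.compartment_percentages()
    assert pct["RCp"] == pytest.approx(50.0)
    sf = shape_factors(s)
    assert sf.ap_ml_ratio["xiphoid"] == pytest.approx(20.0 / 28.0)
    assert sf.surface_to_volume_cm1 == pytest.approx(4000.0 / 21000.0)
    assert sf.height_to_perimeter_xiphoid == pytest.approx(50.0 / 90.0)


def test_volume_error_signs():
    e = volume_error(10.0, 9.5)
    assert e["absolute"] == pytest.approx(0.5)
    assert e["percent"] == pytest.approx(5.0)
    assert volume_error(10.0, 10.5)["percent"] == pytest.approx(-5.0)
    with pytest.raises(GeometryError):
        volume_error(0.0, 1.0)


def test_volume_trace_matches_per_frame_meshes(layout, short_session):
    from thoraco import mesh_from_frame

    _, trajs, _ = short_session
    sub = trajs.positions[:25]
    trace = volume_trace_l(sub, layout, "trunk")
    for k in (0, 10, 24):
        direct = mesh_from_frame(sub[k], layout).signed_volume_mm3() * 1e-6
        assert trace[k] == pytest.approx(direct, rel=1e-12)
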