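import numpy as np
import pytest
import trimesh

from thoraco import (COMPARTMENTS, add_closure_markers, build_compartment_mesh,
                     build_scope_mesh, build_trunk_mesh,
                     compute_reference_levels, mesh_from_frame)
from thoraco.trunk_mesh import MeshBuildError, _zip_rings


def test_closure_markers_are_means(layout, short_session):
    _, trajs, _ = short_session
    frame = trajs.frame(0)
    closed = add_closure_markers(frame, layout, "trunk")
    np.testing.assert_allclose(
        closed.top, frame[layout.row_indices(1)].mean(axis=0))
    np.testing.assert_allclose(
        closed.bottom, frame[layout.row_indices(7)].mean(axis=0))
    np.testing.assert_allclose(
        closed.virtual[2], frame[layout.lateral_indices("right")].mean(axis=0))
    np.testing.assert_allclose(
        closed.virtual[3], frame[layout.lateral_indices("left")].mean(axis=0))


def test_compartment_closure_uses_only_scope_rows(layout, short_session):
    _, trajs, _ = short_session
    frame = trajs.frame(0)
    closed = add_closure_markers(frame, layout, "RCp")
    lo, hi = layout.compartment_rows["RCp"]
    np.testing.assert_allclose(
        closed.top, frame[layout.row_indices(lo)].mean(axis=0))
    np.testing.assert_allclose(
        closed.bottom, frame[layout.row_indices(hi)].mean(axis=0))


def test_trunk_mesh_canonical_counts(trunk0):
    # Euler's formula for a closed genus-0 triangulation forces
    # F = 2V - 4 and E = 3V - 6 once V = 89 + 4 = 93
    assert trunk0.n_vertices == 93
    assert trunk0.n_faces == 182
    assert trunk0.n_edges == 273
    assert trunk0.euler_characteristic() == 2


def test_trunk_mesh_watertight_oriented_outward(trunk0):
    assert trunk0.is_watertight()
    assert trunk0.is_oriented()
    assert trunk0.signed_volume_mm3() > 0
    # trimesh as an independent oracle
    tm = trimesh.Trimesh(trunk0.vertices, trunk0.faces, process=False)
    assert tm.is_watertight
    assert tm.is_winding_consistent
    assert tm.volume == pytest.approx(trunk0.signed_volume_mm3(), rel=1e-12)


def test_topology_frame_independent(layout, short_session):
    """Every frame of a session maps to the identical face array, the
    prerequisite for vertex-correspondence vector fields."""
    _, trajs, _ = short_session
    m0 = mesh_from_frame(trajs.frame(0), layout)
    for k in (100, 500, trajs.n_frames - 1):
        mk = mesh_from_frame(trajs.frame(k), layout)
        assert m0.same_topology(mk)


def test_compartment_meshes_closed(layout, short_session):
    _, trajs, _ = short_session
    frame = trajs.frame(0)
    for comp in COMPARTMENTS:
        m = build_compartment_mesh(frame, layout, comp)
        assert m.is_watertight()
        assert m.euler_characteristic() == 2
        assert m.signed_volume_mm3() > 0


def test_compartment_volumes_roughly_partition_trunk(layout, clean_session):
    """Shared-boundary compartments stack; their summed volume matches the
    trunk within the closure-cap discretization (a few percent)."""
    _, trajs, _ = clean_session
    frame = trajs.frame(0)
    vt = mesh_from_frame(frame, layout).signed_volume_mm3()
    vs = sum(build_compartment_mesh(frame, layout, c).signed_volume_mm3()
             for c in COMPARTMENTS)
    assert vs == pytest.approx(vt, rel=0.08)


def test_original_marker_vertices_preserved(layout, short_session):
    _, trajs, _ = short_session
    frame = trajs.frame(3)
    mesh = mesh_from_frame(frame, layout)
    origin = mesh.provenance["origin_ids"]
    assert len(origin) == layout.total_markers
    for marker_idx, vertex_id in origin.items():
        np.testing.assert_allclose(mesh.vertices[vertex_id], frame[marker_idx])


def test_reference_levels_ordered(layout, short_session):
    _, trajs, _ = short_session
    levels = compute_reference_levels(trajs.frame(0), layout)
    assert levels.z_louis > levels.z_xiphoid > levels.z_umbilicus


def test_zip_rings_equal_and_unequal():
    up_az = np.array([0.0, 90.0, 180.0, 270.0])
    lo_az = np.array([0.0, 72.0, 144.0, 216.0, 288.0])
    faces = _zip_rings(np.arange(4), up_az, 4 + np.arange(5), lo_az)
    assert len(faces) == 9  # m + n triangles
    # every upper-upper edge and lower-lower edge used exactly once
    flat = np.array(faces)
    assert flat.min() >= 0 and flat.max() <= 8
    # strip is a closed band: each boundary vertex appears in >= 2 faces
    counts = np.bincount(flat.ravel(), minlength=9)
    assert counts.min() >= 2


def test_build_rejects_wrong_frame_shape(layout):
    with pytest.raises(MeshBuildError):
        add_closure_markers(np.zeros((10, 3)), layout)


def test_trunk_scope_guard(layout, short_session):
    _, trajs, _ = short_session
    closed = add_closure_markers(trajs.frame(0), layout, "RCp")
    with pytest.raises(MeshBuildError):
        build_trunk_mesh(closed, layout)
    # but the generic builder accepts it
    assert build_scope_mesh(closed, layout).is_watertight()
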