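"""Mesh and marker geometry: volumes, areas, sections, diameters, shape factors.

Units follow the conventions of chest-wall reporting: internal geometry is
in mm; lengths are reported in cm, section/surface areas in dm^2 and
volumes in liters. Volumes of closed meshes use the divergence theorem
(exact for polyhedra); transverse sections are horizontal plane cuts
chained into closed polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .layout import LEVELS, MarkerLayout
from .mesh import TriangleMesh
from .trunk_mesh import ClosedMarkerFrame, add_closure_markers

MM_TO_CM = 0.1
MM2_TO_DM2 = 1e-4
MM3_TO_L = 1e-6


class GeometryError(ValueError):
    pass


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in liters (divergence theorem)."""
    if not mesh.is_watertight():
        raise GeometryError("volume of a non-watertight mesh is undefined")
    v = mesh.signed_volume_mm3()
    if v < 0:
        warnings.warn("mesh was inward-oriented; repairing", stacklevel=2)
        mesh.ensure_outward()
        v = -v
    return v * MM3_TO_L


def mesh_surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in dm^2."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    n_degen = int(np.sum(areas <= 0))
    if n_degen:
        warnings.warn(f"{n_degen} zero-area faces", stacklevel=2)
    return float(areas.sum()) * MM2_TO_DM2


# ---------------------------------------------------------------------------
# Plane sections
# ---------------------------------------------------------------------------

@dataclass
class SectionPolygon:
    """A closed transverse section polygon at height z."""

    points_mm: np.ndarray  # (N, 2) xy vertices, ordered around the loop
    z_mm: float
    area_dm2: float
    perimeter_cm: float


def _loop_metrics(pts: np.ndarray) -> tuple[float, float]:
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    per = float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())
    return float(area), per


def plane_section(mesh: TriangleMesh, z: float,
                  nudge: float = 1e-6) -> SectionPolygon:
    """Cut the mesh with the horizontal plane at height ``z`` (mm).

    Intersection segments are chained combinatorially through shared
    crossing edges into closed loops; the largest-area loop is reported.
    If the plane passes exactly through a vertex it is nudged by
    ``nudge`` mm (declared tie-break) until the cut is transversal.
    """
    zmin, zmax = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    if not zmin < z < zmax:
        raise GeometryError(f"z={z} outside mesh extent ({zmin}, {zmax})")
    zc = z
    for _ in range(50):
        if np.all(np.abs(mesh.vertices[:, 2] - zc) > 1e-12):
            break
        zc += nudge
    d = mesh.vertices[:, 2] - zc

    faces = mesh.faces
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    edges, slot_edge = np.unique(e, axis=0, return_inverse=True)
    crossing = d[edges[:, 0]] * d[edges[:, 1]] < 0
    if not crossing.any():
        raise GeometryError(f"plane z={z} does not intersect the surface")

    denom = np.where(crossing, d[edges[:, 0]] - d[edges[:, 1]], 1.0)
    t = np.where(crossing, d[edges[:, 0]] / denom, 0.0)
    pts = mesh.vertices[edges[:, 0]] + t[:, None] * (
        mesh.vertices[edges[:, 1]] - mesh.vertices[edges[:, 0]]
    )

    slot_edge = slot_edge.reshape(3, -1).T  # (F, 3) edge id per face slot
    cross_per_face = crossing[slot_edge]
    n_cross = cross_per_face.sum(axis=1)
    if not np.all(np.isin(n_cross, (0, 2))):
        raise GeometryError("degenerate cut; non-manifold intersection")
    cut_faces = np.nonzero(n_cross == 2)[0]
    # pair of crossing edges per cut face
    pair = np.array([slot_edge[f][cross_per_face[f]] for f in cut_faces])

    # walk: edge -> its two cut faces
    from collections import defaultdict
    edge_faces: dict[int, list[int]] = defaultdict(list)
    for fi, (ea, eb) in zip(cut_faces, pair):
        edge_faces[int(ea)].append(int(fi))
        edge_faces[int(eb)].append(int(fi))
    face_pair = {int(fi): (int(ea), int(eb)) for fi, (ea, eb) in zip(cut_faces, pair)}

    unvisited = set(face_pair)
    loops: list[list[int]] = []
    while unvisited:
        f0 = min(unvisited)
        loop_edges = []
        f, e_in = f0, face_pair[f0][0]
        while True:
            unvisited.discard(f)
            ea, eb = face_pair[f]
            e_out = eb if e_in == ea else ea
            loop_edges.append(e_out)
            nbrs = [g for g in edge_faces[e_out] if g != f]
            if not nbrs:
                raise GeometryError("open intersection chain (non-watertight?)")
            f, e_in = nbrs[0], e_out
            if f == f0:
                break
        loops.append(loop_edges)

    best, best_metrics = None, (-1.0, 0.0)
    for loop in loops:
        poly = pts[loop][:, :2]
        area, per = _loop_metrics(poly)
        if area > best_metrics[0]:
            best, best_metrics = poly, (area, per)
    return SectionPolygon(
        points_mm=best,
        z_mm=float(z),
        area_dm2=best_metrics[0] * MM2_TO_DM2,
        perimeter_cm=best_metrics[1] * MM_TO_CM,
    )


# ---------------------------------------------------------------------------
# Marker-based lengths
# ---------------------------------------------------------------------------

def level_diameters(frame: np.ndarray, layout: MarkerLayout,
                    level: str) -> dict[str, float]:
    """Antero-posterior and medio-lateral diameters (cm) at a reference level.

    AP is the distance between the front-central and back-central markers
    of the level's row; ML between the right and left lateral markers.
    """
    frame = np.asarray(frame, dtype=float)
    if level not in layout.level_rows:
        raise GeometryError(f"unknown level {level!r}")
    row = layout.level_rows[level]
    fc = layout.central_index(row, "front")
    bc = layout.central_index(row, "back")
    lat_r = layout.lateral_indices("right", (row, row))
    lat_l = layout.lateral_indices("left", (row, row))
    if lat_r.size == 0 or lat_l.size == 0:
        raise GeometryError(f"row {row} lacks lateral markers for ML diameter")
    ap = float(np.linalg.norm(frame[fc] - frame[bc])) * MM_TO_CM
    ml = float(np.linalg.norm(frame[lat_r[0]] - frame[lat_l[0]])) * MM_TO_CM
    return {"AP": ap, "ML": ml}


def trunk_height(closed: ClosedMarkerFrame) -> float:
    """|z_top - z_bottom| of the closure virtuals, in cm."""
    return float(abs(closed.top[2] - closed.bottom[2])) * MM_TO_CM


# ---------------------------------------------------------------------------
# Summaries and shape factors
# ---------------------------------------------------------------------------

@dataclass
class GeometrySummary:
    """Trunk geometry at one respiratory phase."""

    phase: str
    trunk_height_cm: float
    diameters_cm: dict[str, dict[str, float]]   # level -> {AP, ML}
    perimeters_cm: dict[str, float]             # level -> perimeter
    areas_dm2: dict[str, float]                 # level -> section area
    surface_area_dm2: float
    volumes_l: dict[str, float]                 # RCp, RCa, AB, CW_sum, CW_obj

    def __post_init__(self) -> None:
        vols = self.volumes_l
        if {"RCp", "RCa", "AB"} <= set(vols):
            vols.setdefault("CW_sum", vols["RCp"] + vols["RCa"] + vols["AB"])

    def compartment_percentages(self) -> dict[str, float]:
        """Compartment volumes as % of their sum (the chest-wall total)."""
        s = self.volumes_l["CW_sum"]
        if s == 0:
            raise GeometryError("zero chest-wall volume")
        return {c: 100.0 * self.volumes_l[c] / s for c in ("RCp", "RCa", "AB")}


@dataclass
class ShapeFactors:
    ap_ml_ratio: dict[str, float]         # per level, dimensionless
    surface_to_volume_cm1: float          # cm^-1
    height_to_perimeter_xiphoid: float    # dimensionless


def shape_factors(summary: GeometrySummary) -> ShapeFactors:
    ratios = {}
    for level in LEVELS:
        d = summary.diameters_cm[level]
        if d["ML"] == 0:
            raise GeometryError(f"zero ML diameter at {level}")
        ratios[level] = d["AP"] / d["ML"]
    vol_cm3 = summary.volumes_l["CW_obj"] * 1000.0
    if vol_cm3 == 0 or summary.perimeters_cm["xiphoid"] == 0:
        raise GeometryError("zero denominator in shape factor")
    area_cm2 = summary.surface_area_dm2 * 100.0
    return ShapeFactors(
        ap_ml_ratio=ratios,
        surface_to_volume_cm1=area_cm2 / vol_cm3,
        height_to_perimeter_xiphoid=(
            summary.trunk_height_cm / summary.perimeters_cm["xiphoid"]
        ),
    )


def volume_error(gold_l: float, model_l: float) -> dict[str, float]:
    """Signed validation error of a model volume against a gold standard.

    absolute = gold - model (L); percent = absolute / gold * 100.
    Model overestimates give negative errors.
    """
    if gold_l <= 0:
        raise GeometryError("gold-standard volume must be positive")
    absolute = gold_l - model_l
    return {"absolute": absolute, "percent": 100.0 * absolute / gold_l}


# ---------------------------------------------------------------------------
# Volume traces over all frames (vectorized)
# ---------------------------------------------------------------------------

def volume_trace_l(positions: np.ndarray, layout: MarkerLayout,
                   scope: str = "trunk", chunk: int = 2000) -> np.ndarray:
    """Level-0 mesh volume (L) at every frame.

    The triangulation is frame-independent, so it is built once from the
    first frame and only the vertices (markers + recomputed virtual
    means) are updated per frame.
    """
    from .trunk_mesh import build_scope_mesh  # local import avoids cycle

    positions = np.asarray(positions, dtype=float)
    mesh0 = build_scope_mesh(add_closure_markers(positions[0], layout, scope), layout)
    faces = mesh0.faces
    origin = mesh0.provenance["origin_ids"]
    marker_global = np.fromiter(origin.keys(), dtype=int)
    marker_local = np.fromiter(origin.values(), dtype=int)

    lo, hi = layout.scope_rows(scope)
    vsets = [
        layout.row_indices(lo),
        layout.row_indices(hi),
        layout.lateral_indices("right", (lo, hi)),
        layout.lateral_indices("left", (lo, hi)),
    ]
    vids = [mesh0.provenance["virtual_ids"][k] for k in ("top", "bottom", "right", "left")]

    T = positions.shape[0]
    out = np.empty(T)
    nv = mesh0.n_vertices
    for start in range(0, T, chunk):
        p = positions[start:start + chunk]
        verts = np.empty((len(p), nv, 3))
        verts[:, marker_local] = p[:, marker_global]
        for vid, idx in zip(vids, vsets):
            verts[:, vid] = p[:, idx].mean(axis=1)
        v0 = verts[:, faces[:, 0]]
        v1 = verts[:, faces[:, 1]]
        v2 = verts[:, faces[:, 2]]
        out[start:start + chunk] = np.einsum("tij,tij->t", v0, np.cross(v1, v2)) / 6.0
    return out * MM3_TO_L
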