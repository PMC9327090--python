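"""Signed per-vertex displacement fields between two respiratory-phase meshes.

Corresponding vertices of two topologically identical meshes (same
subject, same subdivision level, two phases) define displacement vectors.
The modulus (cm) is signed by an inside/outside test of the vector's
endpoint against the starting volume: endpoints inside the start mesh
(generalized winding number > 1/2) are paradoxical inward motion and get
a negative sign. Three fields describe a subject: FRC->FRCVT (tidal
volume), FRC->TLC (inspiratory capacity) and TLC->RV (vital capacity).

For group displays, fields are jointly rescaled by the maximum absolute
modulus over all subjects, mapping values into [-1, 1] while keeping 0 at
0 so the inward/outward color semantics survive normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .mesh import TriangleMesh

MM_TO_CM = 0.1
PHASE_PAIRS = ("FRC:FRCVT", "FRC:TLC", "TLC:RV")


class VectorFieldError(ValueError):
    pass


@dataclass
class VectorField:
    start_points: np.ndarray   # (N, 3) mm
    end_points: np.ndarray     # (N, 3) mm
    modulus_cm: np.ndarray     # (N,) signed, cm
    faces: np.ndarray          # triangles of the start mesh
    phase_pair: str
    subject_id: str = ""

    @property
    def n_vertices(self) -> int:
        return int(self.start_points.shape[0])

    @property
    def vectors_mm(self) -> np.ndarray:
        return self.end_points - self.start_points


def generalized_winding_number(points: np.ndarray, mesh: TriangleMesh,
                               chunk: int = 256) -> np.ndarray:
    """Generalized winding number of each point w.r.t. a closed mesh.

    Sum of signed solid angles of the faces (van Oosterom-Strackee) over
    4*pi: ~1 inside, ~0 outside, 1/2 on the surface. Robust for
    watertight meshes regardless of local degeneracies.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", b, c) * la
               + np.einsum("pfi,pfi->pf", c, a) * lb)
        out[s:s + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


def build_vector_field(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                       phase_pair: str, subject_id: str = "") -> VectorField:
    """Unsigned displacement field from mesh_a to mesh_b (same topology)."""
    if not mesh_a.same_topology(mesh_b):
        raise VectorFieldError("meshes are not topologically identical")
    vec = mesh_b.vertices - mesh_a.vertices
    return VectorField(
        start_points=mesh_a.vertices.copy(),
        end_points=mesh_b.vertices.copy(),
        modulus_cm=np.linalg.norm(vec, axis=1) * MM_TO_CM,
        faces=mesh_a.faces.copy(),
        phase_pair=phase_pair,
        subject_id=subject_id,
    )


def assign_signs(vf: VectorField, mesh_a: TriangleMesh,
                 zero_tol_cm: float = 1e-7) -> VectorField:
    """Negate the modulus of vectors whose endpoint lies inside the start
    volume (inward, paradoxical motion). Zero-length vectors keep 0, and
    endpoints on the surface count as outward."""
    if not mesh_a.is_watertight():
        raise VectorFieldError("start mesh must be watertight for the sign test")
    w = generalized_winding_number(vf.end_points, mesh_a)
    moving = np.abs(vf.modulus_cm) > zero_tol_cm
    inside = (w > 0.5 + 1e-6) & moving
    modulus = np.abs(vf.modulus_cm)
    modulus[~moving] = 0.0
    modulus[inside] *= -1.0
    return replace(vf, modulus_cm=modulus)


def normalize_fields(fields: list[VectorField]
                     ) -> tuple[list[VectorField], float]:
    """Jointly rescale moduli into [-1, 1] by the shared max |modulus|.

    Returns the normalized fields and the shared scale (cm). Zero maps to
    zero, so subjects keep their relative motion amplitudes.
    """
    if not fields:
        raise VectorFieldError("no fields to normalize")
    for f in fields[1:]:
        if f.modulus_cm.shape != fields[0].modulus_cm.shape:
            raise VectorFieldError("fields have mismatched topology")
    scale = max(float(np.abs(f.modulus_cm).max()) for f in fields)
    if scale == 0:
        warnings.warn("all-zero vector fields; scale is 0", stacklevel=2)
        return [replace(f, modulus_cm=f.modulus_cm.copy()) for f in fields], 0.0
    return [replace(f, modulus_cm=f.modulus_cm / scale) for f in fields], scale


def interpolate_meshes(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                       alpha: float) -> TriangleMesh:
    """Linear blend of corresponding vertices (morphing between phases)."""
    if not 0.0 <= alpha <= 1.0:
        raise VectorFieldError(f"alpha={alpha} outside [0, 1]")
    if not mesh_a.same_topology(mesh_b):
        raise VectorFieldError("meshes are not topologically identical")
    v = (1.0 - alpha) * mesh_a.vertices + alpha * mesh_b.vertices
    return TriangleMesh(v, mesh_a.faces.copy(), dict(mesh_a.provenance))


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def export_vector_field(vf: VectorField, path: str | Path) -> None:
    """Write the field as a plain-text table plus the start-mesh faces.

    Columns: vertex id, start xyz (mm), end xyz (mm), signed modulus (cm).
    """
    with open(path, "w") as fh:
        fh.write(f"# phase_pair: {vf.phase_pair}\n")
        fh.write(f"# subject: {vf.subject_id}\n")
        fh.write("# units: points mm, modulus cm (signed, inward negative)\n")
        fh.write("# columns: id sx sy sz ex ey ez modulus\n")
        for i in range(vf.n_vertices):
            s = vf.start_points[i]
            e = vf.end_points[i]
            fh.write(
                f"{i} {s[0]:.6f} {s[1]:.6f} {s[2]:.6f} "
                f"{e[0]:.6f} {e[1]:.6f} {e[2]:.6f} {vf.modulus_cm[i]:.8f}\n"
            )
        fh.write("# faces\n")
        for f in vf.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


def import_vector_field(path: str | Path) -> VectorField:
    meta = {"phase_pair": "", "subject": ""}
    rows, faces = [], []
    section = "data"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = value.strip()
                elif key == "faces":
                    section = "faces"
                continue
            if section == "data":
                rows.append([float(x) for x in line.split()])
            else:
                faces.append([int(x) for x in line.split()])
    if not rows:
        raise VectorFieldError(f"{path}: no vector rows")
    arr = np.asarray(rows)
    return VectorField(
        start_points=arr[:, 1:4],
        end_points=arr[:, 4:7],
        modulus_cm=arr[:, 7],
        faces=np.asarray(faces, dtype=np.int64),
        phase_pair=meta["phase_pair"],
        subject_id=meta["subject"],
    )
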