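"""Closed triangle-mesh container and topological/orientation checks.

All coordinates are in millimetres. Meshes produced by this package are
watertight genus-0 surfaces (trunk or compartment shells) with outward,
consistently wound faces, so that signed volumes are positive and the
divergence-theorem volume is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TriangleMesh:
    """A triangulated surface.

    Attributes
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices, counter-clockwise seen
        from outside when the mesh is correctly oriented.
    provenance : free-form metadata. Keys used by the pipeline:
        ``level`` (subdivision iteration count), ``origin_ids`` (mapping
        original marker index -> vertex index), ``scope`` (trunk / RCp /
        RCa / AB), ``level_marker_vertex_ids`` (vertex ids of the markers
        in the three anatomical reference rows, used for centering).
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")

    # -- counts ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, shape (E, 2), sorted pairs."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @property
    def n_edges(self) -> int:
        return int(self.edges_unique().shape[0])

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    # -- topology checks ------------------------------------------------
    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_oriented(self) -> bool:
        """True iff each undirected edge is traversed once per direction."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def signed_volume_mm3(self) -> float:
        """Signed volume via the divergence theorem, sum of tetra determinants / 6."""
        v0 = self.vertices[self.faces[:, 0]]
        v1 = self.vertices[self.faces[:, 1]]
        v2 = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)

    def ensure_outward(self) -> "TriangleMesh":
        """Flip all faces if the signed volume is negative. Returns self."""
        if self.signed_volume_mm3() < 0:
            self.faces = self.faces[:, ::-1].copy()
        return self

    def validate(self) -> None:
        """Raise ValueError on any broken closed-surface invariant."""
        if not self.is_watertight():
            raise ValueError("mesh is not watertight (open or non-manifold edges)")
        if not self.is_oriented():
            raise ValueError("mesh winding is not consistent")
        chi = self.euler_characteristic()
        if chi != 2:
            raise ValueError(f"Euler characteristic {chi} != 2 (not genus 0)")
        if self.signed_volume_mm3() <= 0:
            raise ValueError("signed volume is not positive (inward orientation)")

    # -- transforms -----------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "TriangleMesh":
        """Return a rigidly transformed / scaled copy (topology shared semantics,
        arrays copied)."""
        v = self.vertices * scale
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy(), dict(self.provenance))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), dict(self.provenance))

    def same_topology(self, other: "TriangleMesh") -> bool:
        return self.faces.shape == other.faces.shape and bool(
            np.array_equal(self.faces, other.faces)
        )


def split_edge(faces: np.ndarray, a: int, b: int, new_id: int) -> np.ndarray:
    """Split the undirected edge (a, b) by inserting vertex ``new_id``.

    The two faces sharing the edge are each replaced by two triangles with
    the same winding, so watertightness, orientation and genus are
    preserved (V+1, F+2, E+3).
    """
    has_a = (faces == a).any(axis=1)
    has_b = (faces == b).any(axis=1)
    hit = np.nonzero(has_a & has_b)[0]
    if hit.size != 2:
        raise ValueError(
            f"edge ({a}, {b}) is shared by {hit.size} faces, expected 2"
        )
    keep = np.delete(faces, hit, axis=0)
    new_faces = []
    for fi in hit:
        f = faces[fi]
        # rotate so the edge occupies the first two slots, in face order
        for k in range(3):
            u, v, w = f[k], f[(k + 1) % 3], f[(k + 2) % 3]
            if {u, v} == {a, b}:
                new_faces.append([u, new_id, w])
                new_faces.append([new_id, v, w])
                break
        else:  # pragma: no cover - guarded by hit test above
            raise AssertionError("edge not found in face")
    return np.concatenate([keep, np.asarray(new_faces, dtype=faces.dtype)])
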