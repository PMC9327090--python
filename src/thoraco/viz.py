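"""3-D heatmaps, arrow plots and significance maps (matplotlib).

Color semantics follow the breathing-motion convention: outward (positive)
displacement is red, inward (negative, paradoxical) displacement is blue,
through a diverging blue-white-red map over a range symmetric about zero.
Rendering is deterministic for fixed inputs (Agg backend, fixed DPI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib import cm  # noqa: E402
from matplotlib.colors import Normalize  # noqa: E402
from mpl_toolkits.mplot3d.art3d import Poly3DCollection  # noqa: E402

from .mesh import TriangleMesh  # noqa: E402
from .statmap import SignificanceMap  # noqa: E402
from .vector_field import VectorField  # noqa: E402

VIEWS = {  # (elev, azim); the subject faces +y
    "front": (0.0, 90.0),
    "back": (0.0, -90.0),
    "left": (0.0, 180.0),
    "right": (0.0, 0.0),
}

DIVERGING_CMAP = "RdBu_r"  # negative -> blue, positive -> red


class VizError(ValueError):
    pass


@dataclass
class RenderSpec:
    """Rendering parameters for one figure."""

    cmap: str = DIVERGING_CMAP
    range_cm: float | None = None   # symmetric limit; None = data max
    view: str = "front"
    size_px: tuple[int, int] = (900, 900)
    dpi: int = 150
    title: str = ""

    def norm(self, values: np.ndarray) -> Normalize:
        lim = self.range_cm
        if lim is None:
            lim = float(np.abs(values).max()) or 1.0
        return Normalize(vmin=-lim, vmax=lim)


def signed_colors(values: np.ndarray, spec: RenderSpec) -> np.ndarray:
    """RGBA colors of signed values through the diverging map; the range
    is symmetric about 0, so sign determines the color half."""
    norm = spec.norm(values)
    return matplotlib.colormaps[spec.cmap](norm(values))


def _new_axes(spec: RenderSpec):
    w, h = spec.size_px
    fig = plt.figure(figsize=(w / spec.dpi, h / spec.dpi), dpi=spec.dpi)
    ax = fig.add_subplot(projection="3d")
    elev, azim = VIEWS.get(spec.view, VIEWS["front"])
    ax.view_init(elev=elev, azim=azim)
    ax.set_axis_off()
    if spec.title:
        ax.set_title(spec.title)
    return fig, ax


def _fit_axes(ax, vertices: np.ndarray) -> None:
    c = vertices.mean(axis=0)
    r = float(np.abs(vertices - c).max()) or 1.0
    ax.set_xlim(c[0] - r, c[0] + r)
    ax.set_ylim(c[1] - r, c[1] + r)
    ax.set_zlim(c[2] - r, c[2] + r)
    ax.set_box_aspect((1, 1, 1))


def _save(fig, path: str | Path, spec: RenderSpec) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=spec.dpi, metadata={"Software": "thoraco"})
    plt.close(fig)
    return path


def render_heatmap(mesh: TriangleMesh, values_cm: np.ndarray,
                   spec: RenderSpec, path: str | Path) -> Path:
    """Surface colored by per-vertex signed displacement (cm) with a color bar."""
    values_cm = np.asarray(values_cm, dtype=float)
    if len(values_cm) != mesh.n_vertices:
        raise VizError(
            f"{len(values_cm)} values for {mesh.n_vertices} vertices"
        )
    face_vals = values_cm[mesh.faces].mean(axis=1)
    fig, ax = _new_axes(spec)
    polys = mesh.vertices[mesh.faces]
    coll = Poly3DCollection(polys, linewidths=0.05, edgecolors="k")
    coll.set_facecolor(signed_colors(face_vals, spec))
    ax.add_collection3d(coll)
    _fit_axes(ax, mesh.vertices)
    mappable = cm.ScalarMappable(norm=spec.norm(values_cm), cmap=spec.cmap)
    fig.colorbar(mappable, ax=ax, shrink=0.6, label="displacement [cm]")
    return _save(fig, path, spec)


def render_arrow_plot(vf: VectorField, spec: RenderSpec, path: str | Path,
                      stride: int = 1) -> Path:
    """Displacement vectors as arrows colored by their signed modulus."""
    if stride < 1:
        raise VizError("stride must be >= 1")
    idx = np.arange(vf.n_vertices)[::stride]
    vec = vf.vectors_mm[idx]
    mod = vf.modulus_cm[idx]
    fig, ax = _new_axes(spec)
    if np.abs(mod).max() == 0:
        import warnings

        warnings.warn("zero-length vector field; no arrows drawn", stacklevel=2)
    else:
        colors = signed_colors(mod, spec)
        s = vf.start_points[idx]
        ax.quiver(s[:, 0], s[:, 1], s[:, 2], vec[:, 0], vec[:, 1], vec[:, 2],
                  colors=colors, linewidth=0.8, arrow_length_ratio=0.25)
    _fit_axes(ax, vf.start_points)
    mappable = cm.ScalarMappable(norm=spec.norm(vf.modulus_cm), cmap=spec.cmap)
    fig.colorbar(mappable, ax=ax, shrink=0.6, label="signed modulus [cm]")
    return _save(fig, path, spec)


def render_significance_map(smap: SignificanceMap, spec: RenderSpec,
                            path: str | Path) -> Path:
    """Averaged model with significant triangles in red (group 1 greater)
    or blue (group 2 greater); the rest uncolored (light grey)."""
    mesh = smap.base_mesh
    fig, ax = _new_axes(spec)
    colors = np.tile(np.array([0.85, 0.85, 0.85, 1.0]), (mesh.n_faces, 1))
    colors[smap.direction == 1] = (0.80, 0.10, 0.10, 1.0)
    colors[smap.direction == -1] = (0.10, 0.25, 0.80, 1.0)
    coll = Poly3DCollection(mesh.vertices[mesh.faces], linewidths=0.05,
                            edgecolors="k")
    coll.set_facecolor(colors)
    ax.add_collection3d(coll)
    _fit_axes(ax, mesh.vertices)
    return _save(fig, path, spec)
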