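"""Trajectory and mesh file I/O.

Trajectory CSV dialect
----------------------
The proprietary motion-capture container is replaced by a documented plain
CSV dialect::

    # unit: mm
    # sample_rate: 60
    time,r1_LR_X,r1_LR_Y,r1_LR_Z,...

One row per frame; one ``<label>_X/_Y/_Z`` column triple per marker.
Coordinates are converted to the canonical internal unit (mm) on load.
Frames with missing (NaN) marker coordinates are linearly interpolated in
time, up to a configurable maximum gap (default 0.5 s); longer gaps are an
error because they would invalidate the volume trace.

STL I/O goes through :mod:`trimesh` with vertex welding and winding/normal
repair, so a write-then-read round trip reproduces topology and signed
volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .layout import MarkerLayout
from .mesh import TriangleMesh

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "dm": 100.0, "m": 1000.0}

MAX_GAP_S = 0.5


class TrajectoryError(ValueError):
    pass


@dataclass
class MarkerTrajectorySet:
    """Labelled 3-D marker positions over time at a fixed sampling rate.

    positions : (T, M, 3) float array, mm
    """

    positions: np.ndarray
    sample_rate: float
    labels: list[str]
    layout: MarkerLayout

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must be (T, M, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise TrajectoryError("marker count does not match labels")
        if self.layout is not None and self.positions.shape[1] != self.layout.total_markers:
            raise TrajectoryError(
                f"{self.positions.shape[1]} markers but layout expects "
                f"{self.layout.total_markers}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def frame(self, k: int) -> np.ndarray:
        return self.positions[k]


def _interpolate_gaps(pos: np.ndarray, sample_rate: float,
                      max_gap_s: float = MAX_GAP_S) -> np.ndarray:
    """Linearly interpolate NaN runs per marker coordinate; error on long gaps."""
    T, M, _ = pos.shape
    max_gap = max(1, int(round(max_gap_s * sample_rate)))
    out = pos.copy()
    t = np.arange(T)
    for m in range(M):
        bad = ~np.isfinite(pos[:, m, :]).all(axis=1)
        if not bad.any():
            continue
        if bad.all():
            raise TrajectoryError(f"marker {m} has no finite frames")
        # longest consecutive run of missing frames
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
        if runs.size and runs.max() > max_gap:
            raise TrajectoryError(
                f"marker {m}: {runs.max()} consecutive missing frames exceeds "
                f"the {max_gap}-frame ({max_gap_s} s) gap policy"
            )
        good = ~bad
        for c in range(3):
            out[bad, m, c] = np.interp(t[bad], t[good], pos[good, m, c])
    return out


def load_trajectories(path: str | Path, layout: MarkerLayout,
                      max_gap_s: float = MAX_GAP_S) -> MarkerTrajectorySet:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos0 = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos0 = fh.tell()
            else:
                fh.seek(pos0)
                break
        df = pd.read_csv(fh)
    if "sample_rate" not in meta:
        raise TrajectoryError(f"{path}: missing '# sample_rate:' header")
    sample_rate = float(meta["sample_rate"])
    unit = meta.get("unit", "mm").lower()
    if unit not in _UNIT_TO_MM:
        raise TrajectoryError(f"{path}: unknown unit {unit!r}")
    scale = _UNIT_TO_MM[unit]

    cols = set(df.columns)
    missing, order = [], []
    for label in layout.marker_labels:
        triple = [f"{label}_{ax}" for ax in "XYZ"]
        if not all(c in cols for c in triple):
            missing.append(label)
        else:
            order.extend(triple)
    if missing:
        raise TrajectoryError(
            f"{path}: layout labels without columns: {', '.join(missing)}"
        )
    extra = cols - set(order) - {"time"}
    if extra:
        raise TrajectoryError(
            f"{path}: columns not in layout: {', '.join(sorted(extra))}"
        )
    pos = df[order].to_numpy(dtype=float).reshape(len(df), layout.total_markers, 3)
    pos = _interpolate_gaps(pos * scale, sample_rate, max_gap_s)
    return MarkerTrajectorySet(pos, sample_rate, layout.marker_labels, layout)


def save_trajectories(trajs: MarkerTrajectorySet, path: str | Path,
                      unit: str = "mm", float_fmt: str = "%.6f") -> None:
    scale = 1.0 / _UNIT_TO_MM[unit.lower()]
    cols = {"time": trajs.times}
    flat = trajs.positions * scale
    for m, label in enumerate(trajs.labels):
        for c, ax in enumerate("XYZ"):
            cols[f"{label}_{ax}"] = flat[:, m, c]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# unit: {unit}\n# sample_rate: {trajs.sample_rate:g}\n")
        df.to_csv(fh, index=False, float_format=float_fmt)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path: str | Path) -> bool:
    """Export to binary STL. Returns True if the mesh was watertight,
    False (with a warning) otherwise -- the file is still written."""
    ok = mesh.is_watertight()
    if not ok:
        warnings.warn(f"writing non-watertight mesh to {path}", stacklevel=2)
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(str(path))
    return ok


def read_stl(path: str | Path, weld_tol: float = 1e-6) -> TriangleMesh:
    """Read an STL (binary or ASCII), weld duplicate vertices and repair
    the winding so the signed volume is positive."""
    tm = _trimesh.load_mesh(str(path), process=False)
    if not isinstance(tm, _trimesh.Trimesh):  # pragma: no cover
        raise IOError(f"{path}: not a triangle mesh")
    tm.merge_vertices(digits_vertex=int(round(-np.log10(weld_tol))))
    _trimesh.repair.fix_normals(tm)
    mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))
    mesh.ensure_outward()
    return mesh
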