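"""End-to-end subject and group workflows.

``run_subject`` chains the stages for one acquisition: trajectories ->
level-0 volume traces (trunk + compartments) -> phase detection ->
ventilatory pattern -> closed meshes at the four static phases ->
subdivision smoothing -> geometry summaries -> the three signed vector
fields (FRC->FRCVT, FRC->TLC, TLC->RV). ``compare_groups`` jointly
normalizes two groups' fields and produces one per-triangle significance
map per ventilatory phase (VT, IC, VC). All parameters and output
checksums are recorded in a JSON run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .breathing import (PhaseVolumes, VentilatoryPattern, VolumeTrace,
                        detect_phases, ventilatory_pattern)
from .geometry import (GeometrySummary, mesh_surface_area, mesh_volume,
                       level_diameters, plane_section, trunk_height,
                       volume_trace_l)
from .layout import COMPARTMENTS, LEVELS, MarkerLayout
from .marker_io import MarkerTrajectorySet, write_stl
from .mesh import TriangleMesh
from .statmap import SignificanceMap, significance_map
from .subdivision import subdivide
from .trunk_mesh import add_closure_markers, build_scope_mesh, compute_reference_levels
from .vector_field import (VectorField, assign_signs, build_vector_field,
                           export_vector_field, normalize_fields)

PHASES = ("RV", "FRC", "FRCVT", "TLC")
PAIR_OF = {"VT": "FRC:FRCVT", "IC": "FRC:TLC", "VC": "TLC:RV"}


@dataclass
class RunManifest:
    tool_version: str
    parameters: dict
    inputs: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "parameters": self.parameters,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                },
                fh, indent=2, sort_keys=True,
            )


@dataclass
class SubjectResult:
    subject_id: str
    trace: VolumeTrace
    phases: PhaseVolumes
    pattern: VentilatoryPattern
    meshes: dict[str, TriangleMesh]            # smoothed trunk mesh per phase
    summaries: dict[str, GeometrySummary]
    fields: dict[str, VectorField]             # phase pair -> signed field
    manifest: RunManifest | None = None


def _phase_summary(frame: np.ndarray, layout: MarkerLayout, phase: str,
                   trunk_smooth: TriangleMesh, level: int) -> GeometrySummary:
    closed = add_closure_markers(frame, layout, "trunk")
    levels = compute_reference_levels(frame, layout)
    diameters = {lv: level_diameters(frame, layout, lv) for lv in LEVELS}
    perims, areas = {}, {}
    for lv, z in levels.as_dict().items():
        sect = plane_section(trunk_smooth, z)
        perims[lv] = sect.perimeter_cm
        areas[lv] = sect.area_dm2
    vols = {}
    for comp in COMPARTMENTS:
        cm = build_scope_mesh(add_closure_markers(frame, layout, comp), layout)
        vols[comp] = mesh_volume(subdivide(cm, level).mesh if level else cm)
    vols["CW_obj"] = mesh_volume(trunk_smooth)
    return GeometrySummary(
        phase=phase,
        trunk_height_cm=trunk_height(closed),
        diameters_cm=diameters,
        perimeters_cm=perims,
        areas_dm2=areas,
        surface_area_dm2=mesh_surface_area(trunk_smooth),
        volumes_l=vols,
    )


def run_subject(trajs: MarkerTrajectorySet, quiet_window_s: float,
                level: int = 1, subject_id: str = "subject",
                outdir: str | Path | None = None,
                summaries: bool = True) -> SubjectResult:
    """Run the full single-subject analysis."""
    layout = trajs.layout
    trace = VolumeTrace(
        t=trajs.times,
        volume_l=volume_trace_l(trajs.positions, layout, "trunk"),
        sample_rate=trajs.sample_rate,
        compartments={
            c: volume_trace_l(trajs.positions, layout, c) for c in COMPARTMENTS
        },
    )
    phases = detect_phases(trace, quiet_window_s)
    pattern = ventilatory_pattern(phases, trace)

    meshes: dict[str, TriangleMesh] = {}
    summ: dict[str, GeometrySummary] = {}
    for phase in PHASES:
        frame = trajs.frame(phases.frames[phase])
        level0 = build_scope_mesh(add_closure_markers(frame, layout, "trunk"), layout)
        smooth = subdivide(level0, level).mesh if level else level0
        meshes[phase] = smooth
        if summaries:
            summ[phase] = _phase_summary(frame, layout, phase, smooth, level)

    fields: dict[str, VectorField] = {}
    for pair in PAIR_OF.values():
        p0, p1 = pair.split(":")
        vf = build_vector_field(meshes[p0], meshes[p1], pair, subject_id)
        fields[pair] = assign_signs(vf, meshes[p0])

    manifest = RunManifest(
        tool_version=__version__,
        parameters={
            "subdivision_level": level,
            "quiet_window_s": quiet_window_s,
            "sample_rate": trajs.sample_rate,
        },
        inputs={"subject_id": subject_id, "n_frames": trajs.n_frames,
                "n_markers": trajs.positions.shape[1]},
    )
    result = SubjectResult(subject_id, trace, phases, pattern, meshes, summ,
                           fields, manifest)
    if outdir is not None:
        _write_subject_outputs(result, Path(outdir))
    return result


def _write_subject_outputs(result: SubjectResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for phase, mesh in result.meshes.items():
        path = outdir / f"{result.subject_id}_{phase}.stl"
        write_stl(mesh, path)
        result.manifest.add_output(path)
    for pair, vf in result.fields.items():
        path = outdir / f"{result.subject_id}_vf_{pair.replace(':', '_')}.txt"
        export_vector_field(vf, path)
        result.manifest.add_output(path)
    phases_path = outdir / f"{result.subject_id}_phases.json"
    with open(phases_path, "w") as fh:
        json.dump(
            {
                "RV_l": result.phases.rv_l,
                "FRC_l": result.phases.frc_l,
                "FRCVT_l": result.phases.frcvt_l,
                "TLC_l": result.phases.tlc_l,
                "frames": result.phases.frames,
                "VT_l": result.pattern.vt_l,
                "IC_l": result.pattern.ic_l,
                "VC_l": result.pattern.vc_l,
                "RR_bpm": result.pattern.rr_bpm,
                "MV_l_min": result.pattern.mv_l_min,
                "compartment_percent": result.pattern.compartment_percent,
            },
            fh, indent=2,
        )
    result.manifest.add_output(phases_path)
    if result.summaries:
        import pandas as pd

        rows = []
        for phase, s in result.summaries.items():
            rows.append(("trunk_height_cm", phase, s.trunk_height_cm))
            for lv in LEVELS:
                rows.append((f"AP_{lv}_cm", phase, s.diameters_cm[lv]["AP"]))
                rows.append((f"ML_{lv}_cm", phase, s.diameters_cm[lv]["ML"]))
                rows.append((f"perimeter_{lv}_cm", phase, s.perimeters_cm[lv]))
                rows.append((f"area_{lv}_dm2", phase, s.areas_dm2[lv]))
            rows.append(("surface_area_dm2", phase, s.surface_area_dm2))
            for k, v in s.volumes_l.items():
                rows.append((f"volume_{k}_l", phase, v))
        df = pd.DataFrame(rows, columns=["quantity", "phase", "value"])
        path = outdir / f"{result.subject_id}_geometry.csv"
        df.to_csv(path, index=False)
        result.manifest.add_output(path)
    result.manifest.write(outdir / f"{result.subject_id}_manifest.json")


def compare_groups(group1: list[SubjectResult], group2: list[SubjectResult],
                   alpha: float = 0.05,
                   outdir: str | Path | None = None
                   ) -> dict[str, SignificanceMap]:
    """Per-triangle significance maps (VT, IC, VC pairs) between two groups."""
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need at least 2 subjects per group")
    maps: dict[str, SignificanceMap] = {}
    for which, pair in PAIR_OF.items():
        f1 = [r.fields[pair] for r in group1]
        f2 = [r.fields[pair] for r in group2]
        normed, _scale = normalize_fields(f1 + f2)
        base = [r.meshes[pair.split(":")[0]] for r in group1 + group2]
        maps[which] = significance_map(
            normed[: len(f1)], normed[len(f1):], alpha=alpha, base_meshes=base
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for which, smap in maps.items():
            with open(outdir / f"statmap_{which}.json", "w") as fh:
                json.dump(
                    {
                        "alpha": smap.alpha,
                        "p_values": smap.p_values.tolist(),
                        "direction": smap.direction.tolist(),
                    },
                    fh,
                )
    return maps
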