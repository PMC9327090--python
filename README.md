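# thoraco

3-D analysis of thoraco-abdominal surface shape and breathing motion from
marker-based (opto-electronic plethysmography style) acquisitions.

## The problem

Spirometry reduces breathing to a single volume signal. Marker-based
chest-wall tracking keeps the geometry: ~90 reflective markers on the
trunk, sampled at 60 Hz, describe *where* the chest wall moves, how the
three compartments — pulmonary ribcage (RCp), abdominal ribcage (RCa) and
abdomen (AB) — share each breath, and whether any region moves
paradoxically (inward during inspiration). `thoraco` turns such marker
trajectories into closed surface models and quantitative descriptors:

1. **Closure + triangulation** — each frame's 89 markers are closed with 4
   virtual markers (top/bottom/right/left, each a recomputable mean of a
   marker subset) and triangulated into a watertight genus-0 mesh with
   exactly 93 vertices, 182 faces and 273 edges. Compartment meshes share
   boundary marker rows, so compartment volumes stack.
2. **Subdivision smoothing** — Catmull-Clark (NURMS-style) subdivision,
   carrying the quad control mesh between iterations; the vertex schedule
   from the trunk mesh is 548, 2 186, 8 738, 34 946, 139 778 for
   iterations 1–5.
3. **Geometry** — divergence-theorem volumes (L), surface areas (dm²),
   transverse plane sections (area, perimeter) at the three anatomical
   reference levels (angle of Louis, xiphoid, umbilicus), AP/ML diameters
   and shape factors.
4. **Breathing** — the per-frame trunk volume trace yields the four static
   phases (RV, FRC, FRCVT, TLC) and the ventilatory pattern
   (VT, IC, VC, RR, MV) with signed compartmental contributions.
5. **Vector fields** — per-vertex displacement between two phase meshes,
   with a sign from a generalized-winding-number inside/outside test:
   motion into the starting volume (paradoxical) is negative.
6. **Statistics** — per-triangle two-group comparison with an exact
   Wilcoxon-Mann-Whitney test (permutation distribution, mid-rank ties),
   painted red/blue on an averaged model.
7. **Phantom** — a synthetic breathing torso (stacked elliptic rings,
   quiet breathing followed by a maximal capacity maneuver) with exact
   analytic ground truth for every quantity above, used for validation.

## Worked example

```python
from thoraco import (PhantomConfig, generate_phantom, mesh_from_frame,
                     subdivide, mesh_volume, run_subject)

# 1. synthesize a session: 3 min quiet breathing + maximal capacity maneuver
cfg = PhantomConfig(seed=42)
trajs, truth = generate_phantom(cfg)
print(f"{trajs.n_frames} frames, {trajs.positions.shape[1]} markers at {trajs.sample_rate:g} Hz")

# 2. close and triangulate the trunk at the first frame
trunk = mesh_from_frame(trajs.frame(0), cfg.layout, "trunk")
print(f"trunk mesh: V={trunk.n_vertices} F={trunk.n_faces} E={trunk.n_edges}, "
      f"watertight={trunk.is_watertight()}")

# 3. smooth by subdivision
res = subdivide(trunk, 3)
print("vertex schedule:", res.vertex_count_history)
print(f"volume: level 0 {mesh_volume(trunk):.2f} L -> level 3 {res.volume_history_l[3]:.2f} L "
      f"(analytic {truth.volume_l[0]:.2f} L)")

# 4. full pipeline: phases, pattern, signed displacement fields
result = run_subject(trajs, quiet_window_s=cfg.quiet_duration_s, level=1, subject_id="demo")
p = result.pattern
print(f"VT={p.vt_l:.2f} L  IC={p.ic_l:.2f} L  VC={p.vc_l:.2f} L  "
      f"RR={p.rr_bpm:.1f} /min  MV={p.mv_l_min:.1f} L/min")
print("VT compartment split [%]:",
      {k: round(v, 1) for k, v in p.compartment_percent["VT"].items()})
vf = result.fields["TLC:RV"]
print(f"TLC->RV field: {(vf.modulus_cm < 0).mean():.0%} of vertices move inward")
```

Output:

```
11341 frames, 89 markers at 60 Hz
trunk mesh: V=93 F=182 E=273, watertight=True
vertex schedule: [93, 548, 2186, 8738]
volume: level 0 21.53 L -> level 3 20.33 L (analytic 22.49 L)
VT=0.54 L  IC=2.63 L  VC=3.66 L  RR=15.0 /min  MV=8.0 L/min
VT compartment split [%]: {'RCp': 44.8, 'RCa': 18.9, 'AB': 36.3}
TLC->RV field: 93% of vertices move inward
```

Note the systematic ~4% underestimation of the absolute enclosed volume:
markers lie *on* the surface, so the triangulated mesh is an inscribed
polyhedron, and subdivision (an approximating scheme) shrinks a convex
surface further. Volume *differences* (VT, IC, VC) are far less affected
because the deficit is nearly proportional.

## Command line

The `thoraco` command mirrors the pipeline stages:

```sh
thoraco phantom subject.csv --seed 42 --truth truth.json   # synthetic acquisition
thoraco validate-input subject.csv                         # check against the layout
thoraco build subject.csv trunk.stl --frame 0              # closed level-0 trunk mesh
thoraco smooth trunk.stl smooth.stl --level 2              # Catmull-Clark
thoraco measure smooth.stl                                 # volume [L], area [dm^2]
thoraco phases subject.csv --quiet-window 180              # RV/FRC/FRCVT/TLC + pattern
thoraco vf frc.stl tlc.stl field.txt --pair FRC:TLC        # signed displacement field
thoraco render field.txt heatmap.png                       # diverging red/blue heatmap
thoraco run subject.csv out/ --quiet-window 180            # everything, with manifest
thoraco compare --group1 a.csv --group1 b.csv \
                --group2 c.csv --group2 d.csv \
                out/ --quiet-window 180                    # per-triangle MWU maps
```

Input trajectories are plain CSV (`# unit:` and `# sample_rate:` header
comments, one `<label>_X/_Y/_Z` column triple per marker); marker layouts
are small YAML files (the built-in default is the 89-marker seated
layout). Meshes are STL; vector fields and statistics are plain text/JSON.

## Reproduction

* `python -m pytest -q tests/` runs the full suite, including
  `tests/test_acceptance.py`, one test per stated acceptance property
  (vertex schedule, volume-shrink trend, volume accuracy, pattern
  recovery, paradox sign detection, exact-MWU oracle equivalence,
  null-map calibration, geometry invariants).
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the subdivision vertex-count targets from scratch (the
  counts are topology-determined and seed-invariant).

Known honest failure: the acceptance clause requiring the *level-1*
(smoothed) phantom volume within 5 % of analytic truth is unattainable
for surface-inscribed markers — the inscribed-polygon deficit (~4.3 % for
12–13 stations per ring) and the first subdivision shrink (~4.1 %) add to
~8.3 %. The level-0 clause passes at 4.2–4.5 %. The corresponding test is
left failing rather than weakened.
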