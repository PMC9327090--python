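# Methods

This note states the quantitative conventions the package implements.
Internal computation is in millimetres; reported lengths are cm, areas
dm², volumes litres.

## Marker layout and closure

The canonical layout places 89 markers on 7 circumferential rows: five
anterior columns (azimuths 150°, 120°, 90°, 60°, 30°), five posterior
columns (210°…330°), one lateral marker per side (0°/180°) on every row,
and one extra anterior station (75°) on rows 3–7. Azimuth 0° is the
subject's right lateral, 90° the anterior centre; row 1 is cranial and z
decreases with row index. Reference levels are rows 2 (angle of Louis),
4 (xiphoid) and 6 (umbilicus). Compartments are inclusive row ranges —
RCp rows 1–4, RCa rows 4–5, AB rows 5–7 — adjacent compartments sharing
their boundary row, so compartment volumes stack into the chest-wall sum.

A frame is closed with four virtual markers, each a recomputable
arithmetic mean: top/bottom = mean of the highest/lowest row in scope;
right/left = mean of that side's lateral column within the scope.

## Triangulation

Rows are closed rings ordered by azimuth. Adjacent rings (12 or 13
stations) are stitched by an angular merge: at each step the triangle is
closed toward whichever ring's next station has the smaller azimuth,
producing m+n outward-wound triangles per band and handling unequal ring
sizes uniformly. Top and bottom virtuals cap the end rings with fans.
Each side virtual is inserted by splitting the *median* vertical edge of
its lateral chain — a layout-only choice, so every frame of a subject
receives the identical face array (vertex i always corresponds across
frames, which the displacement fields require). For 89 markers this
yields V=93, F=182, E=273; for a closed genus-0 triangulation Euler's
formula forces F=2V−4 and E=3V−6, so the counts are a structural
invariant, checked on every build together with watertightness (every
edge in exactly two faces), consistent winding and positive volume.

## Subdivision smoothing

Smoothing is Catmull-Clark subdivision with standard closed-surface
weights: face point = vertex mean; edge point = mean of the two endpoints
and two adjacent face points; old vertex → (Q + 2R + (n−3)S)/n. Each
iteration creates V′ = V + E + F vertices and one quad per face corner;
the quad control mesh is carried between iterations (triangulating
between levels would change the schedule), giving 548, 2 186, 8 738,
34 946, 139 778 vertices from the trunk mesh. The triangle mesh returned
to callers splits each quad along its (vertex-point, face-point)
diagonal, which adds no positions. Old vertices keep their indices, so
marker provenance survives smoothing; the scheme is approximating
(vertices are repositioned and a convex surface shrinks, by ~4.1 % then
~1.3 %, ~0.3 %, ~0.09 % of volume on the trunk), with an optional
interpolating mode that pins the original marker positions.

## Geometry

Closed-mesh volume uses the divergence theorem, ∑ det(v0,v1,v2)/6 over
triangles — exact for polyhedra. Transverse sections chain the mesh-plane
intersection segments combinatorially through shared crossing edges into
closed loops (the plane is nudged 10⁻⁶ mm off any vertex); the
largest-area loop supplies shoelace area and perimeter. AP diameter is
the front-centre to back-centre marker distance of a level's row, ML the
lateral-to-lateral distance. Shape factors: AP/ML per level,
surface-to-volume (cm⁻¹), trunk height over xiphoid perimeter.

## Breathing

The trunk volume trace is evaluated on the level-0 mesh at every frame
(the triangulation is frame-independent, so only vertices update). A
0.25 s moving mean is used for extremum *detection* only; two
`find_peaks` passes (the first permissive, the second at 25 % of the
median quiet excursion as prominence) locate quiet-breathing peaks and
troughs. FRC and FRCVT are medians of the raw trough/peak values (robust
to drift); TLC and RV are the global extremes of the maneuver. Pattern:
VT = FRCVT−FRC, IC = TLC−FRC, VC = TLC−RV, RR = 60/mean trough-to-trough
period, MV = VT·RR. Compartment contributions are the compartment-trace
differences at the phase instants, as signed percentages of their sum —
negative values flag paradoxical motion.

## Displacement fields and signs

Two same-topology meshes (one subject, two phases) define per-vertex
displacement vectors; the modulus is |v| in cm. The sign comes from a
generalized winding number (sum of van Oosterom–Strackee signed solid
angles over 4π) of the vector's endpoint with respect to the starting
surface: endpoints inside (w > ½) are inward, paradoxical motion and get
a negative modulus; zero-length vectors stay 0; surface points count as
outward. For group displays all subjects' fields are rescaled jointly by
the shared maximum |modulus|, mapping into [−1, 1] while preserving 0.

## Statistics

For each triangle the per-subject scalar is the mean |modulus| of its
three vertices. Groups are compared with a two-sided
Wilcoxon–Mann–Whitney test, exact for combined n ≤ 20: the permutation
distribution of the rank sum is built by subset-sum dynamic programming
over doubled mid-ranks (handling ties exactly), and the two-sided p is
twice the smaller tail, capped at 1. Larger samples use the normal
approximation with tie and continuity corrections. Significant triangles
(p < α, default 0.05, optional Benjamini–Hochberg adjustment) are painted
red where group 1 moves more and blue where group 2 does, on an averaged
model built from centred, vertex-wise-averaged subject meshes. At
n = m = 5 the attainable exact-test size at α = 0.05 is 12/252 ≈ 0.048.

## Validation phantom

The phantom is a stack of elliptic rings at the 7 row heights with
linear-in-z interpolation, breathing via a radial gain
u = 1 + ε_row·s(t)·g(θ), where s(t) is a sinusoid (quiet phase) followed
by continuous linear ramps to the TLC excursion, down to the RV excursion
and back, and g(θ) = ((1+asym) + (1−asym)cosθ)/2 is a smooth left/right
asymmetry gain. Paradox-flagged compartments flip ε. Cross-section areas
have exact closed forms (πab(α² + β²/2) with α = 1 + εs(1+asym)/2,
β = εs(1−asym)/2 when both half-axes are gained), and the z-integral is a
polynomial of degree ≤ 4 per segment, integrated exactly by 3-point Gauss
quadrature — so every reported quantity has analytic ground truth.
Defaults describe a healthy adult study session: ~22 L chest wall,
15 breaths/min for 3 min, VT ≈ 0.5 L, IC ≈ 2.7 L, VC ≈ 3.8 L, 60 Hz
sampling, 0.3 mm marker jitter.

Because the markers lie *on* the analytic surface, the level-0 mesh is an
inscribed polyhedron and underestimates the true volume by ~4.3 % (12–13
stations per ring); subdivision adds its ~4.1 % first-iteration shrink.
Capacities (volume differences) are nearly unaffected, since the deficit
is close to proportional.
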