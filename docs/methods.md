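# Methods

This note records how `aneumorph` defines and discretizes each quantity,
the estimator and tolerance choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations. Units are millimetres throughout; no unit metadata is read
from mesh files.

## Mesh model and validation

A `TriangleSurface` is an indexed triangle mesh whose topology is
checked on construction: every edge may be shared by at most two
triangles (manifold), vertices closer than 1e-9 mm are merged, and
exactly degenerate triangles (repeated indices after merging) are
dropped. Orientation is made globally consistent by breadth-first
propagation across shared edges; the *global* sign is fixed at the
`AneurysmDome` level by temporarily capping the neck and flipping all
triangles if the signed volume is negative, so normals always point
away from the enclosed blood volume. This automates the deterministic
part of orientation repair; everything else (self-intersections,
non-manifold edges, hole counts) is reported by `validate_surface` but
never silently fixed — the validator never deforms geometry.
Self-intersection testing is an exact triangle–triangle interval test
over axis-aligned-bounding-box-filtered pairs; pairs sharing a vertex
are excluded since adjacent triangles touch by construction.

A dome is an open surface with exactly one boundary loop — the neck
curve. Closing it (`cap_neck`) fans the loop to its arc-length-weighted
centroid. The fan is deterministic and robust for star-shaped loops;
strongly non-planar loops (out-of-plane extent above half the in-plane
extent) trigger a warning because the fan may fold. The cap triangles
are flagged so that `A` (dome only) and `A_closed` (dome + cap) are
both available, with `area(non-cap) == area(dome)` exactly.

## Size and neck parameters

* `H` is the maximum *signed* height of dome vertices above the neck
  plane — points below the plane (overhanging necks) are ignored for
  the maximum rather than producing negative heights.
* The neck plane is the total-least-squares plane through the boundary
  loop with *arc-length* vertex weights, so the fit does not depend on
  how densely each part of the loop is sampled. Its origin, the
  arc-length centroid of the loop, is also the reference point for
  `H_max` ("centroid of the neck").
* `D_max` (#4) is localized: the dome is sliced at 100 heights
  (k + ½)H/100 strictly above the neck plane, the per-slice diameter is
  the maximum pairwise distance among plane–mesh intersection points,
  and `H_b` (#5) is the height of the maximizing slice (lowest slice on
  ties). The slice count is configurable; 100 puts the height
  quantization at H/100 ≈ 0.03–0.05 mm for typical aneurysms, well
  below reconstruction variability. Note that where the diameter
  profile is flat (e.g. near the equator of a sphere-like sac) the
  argmax is intrinsically ill-conditioned: mesh chord noise of order
  1e-3 relative can move `H_b` by `sqrt(2R · noise)`, which is why
  tests on analytic caps allow ~0.1 mm slack on `H_b` but 0.2 % on
  `D_max` itself.
* "Minimum distance between two opposite points on the neck perimeter"
  (#13) is implemented as the minimal caliper width of the projected
  loop's 2D convex hull (rotating calipers): deterministic,
  rotation-invariant, and equal to the intuitive caliper measurement.
  `D_neck,max` uses projected points; `P_neck` is the 3D polyline
  length (a perimeter is a curve property; a diameter is a footprint
  property). `A_neck` is the planar projected-polygon (shoelace) area —
  the hydraulic-diameter formula `D_neck,equiv = 4A/P` presumes a
  planar cross-section. A self-intersecting projected polygon falls
  back to its convex hull area and is flagged in the record.
* Convex hull and minimal bounding sphere are computed on the vertex
  set: the extremal points of a triangulated surface are vertices, so
  facet sampling adds nothing. The hull is qhull's exact hull; the
  bounding sphere is a Welzl-type move-to-front algorithm with
  2/3/4-point support sets, with a final corrective pass enforcing the
  all-vertices-within-radius+1e-9 contract. The bounding sphere of the
  published parameters is always the sphere of the *vertex set* of the
  open dome.

## Dimensionless indices

`UI = 1 − CR` and `NSI = 1 − (18π)^(1/3)/IPR` hold as exact identities
of the implementation, which is why Kendall τ between the paired
indices is ±1 on any tie-free cohort — a structural property, useful as
an end-to-end pipeline check.

The surface area entering `NSI`, `IPR` and `AASA` is `A_closed`, not
the dome-only area: these normalizations are defined for closed bodies,
and only this choice makes the index values of simple closed shapes
(hemisphere: NSI = 1/3, IPR = 5.758, AASA = 3/4) come out at their
standard reference values. `EI` uses the convex hull's own (closed)
area and volume. `SR` uses `H_max` over the user-supplied parent-vessel
diameter; the parent vessel is not part of the extracted dome, so the
diameter is a per-aneurysm scalar input and `SR` is simply absent when
it is not provided.

## Curvature

Gaussian curvature is the angle deficit `(2π − Σ incident angles)/w`;
mean curvature is the norm of the cotangent mean-curvature vector over
`4w`, signed by its alignment with the outward vertex normal (convex
outward = positive). The vertex area `w` is the mixed Voronoi area
(Voronoi for non-obtuse triangles, area/2 at the obtuse corner and
area/4 elsewhere otherwise; exactly degenerate triangles fall back to
barycentric thirds and set a flag). These choices make Σw equal the
total surface area exactly and satisfy Gauss–Bonnet (ΣwK = 4π on a
closed genus-0 mesh) to rounding.

Statistics use interior vertices only: vertices on, or sharing a
triangle with, the neck boundary are masked, because the discrete
operators are meaningless at an open boundary and the neck crease is an
artifact of sac extraction. Area-weighted interior means give `MAA`,
`absMAA`, `MSD`, `GAA`, `absGAA`, `GSD`. The L2-norm indices are
estimated as interior means times the *full* dome area,
`MLN = sqrt(A·⟨M²⟩)/4π` and `GLN = sqrt(A·(A·⟨K²⟩))/4π`, rather than as
raw masked sums: dropping the boundary ring from an integral biases it
low by the ring area fraction, while the mean-times-area estimator
converges cleanly (hemisphere: MLN → sqrt(2π)/4π ≈ 0.1995, GLN → 1/2; a
full sphere gives 0.2821 and 1). `HMC = 100(absMAA·r_MBS − 1)` and
`HGC = 100(absGAA·r_MBS² − 1)` compare the average absolute curvatures
against those of the minimal bounding sphere, in percent; both vanish
for a shape that is its own bounding sphere cap.

Verification anchors: constant-curvature sphere and cylinder fixtures
(2 % at 0.05R resolution), an analytic height-field patch checked
against the fundamental-form formulas (5 %), Gauss–Bonnet (1e-6), and
refinement convergence.

## Uncertainty quantification

Per parameter and aneurysm: median, absolute uncertainty =
P84.13 − P15.87 (the middle 68.3 % range, ±1 SD for normal data),
relative uncertainty = 100 · range/median (undefined and flagged when
the median is 0). Across aneurysms both the medians and the relative
uncertainties are summarized as median [IQR] — never means — plus the
Kendall τ-b between the per-aneurysm medians and relative
uncertainties, and an OLS regression of the absolute range on the
median. Absolute relative deviations `|x − median|/median` per record
feed boxplot summaries with Tukey 1.5·IQR whiskers and a count of
deviations above 100 %.

The percentile estimator matters at n ≈ 25: the default interpolates at
position (n+1)q with clamping at the extremes (the estimator used by
SPSS), and plain linear interpolation is selectable
(`--percentile-method linear`). The IQRs use the same estimator. The
Wilcoxon signed-rank test drops zero differences, uses the exact null
distribution for n ≤ 25 and the continuity-corrected normal
approximation above; identical inputs are reported as the degenerate
(0, p = 1) rather than an error. Kendall τ-b carries the standard tie
correction and refuses all-tied input. No multiple-testing correction
is applied anywhere; p-values are raw, α = 0.05.

## Synthetic data

`make_spherical_cap` triangulates concentric rings in an
azimuthal-equidistant projection (Delaunay in the disk) and maps them
to the sphere, so *every vertex lies exactly on the analytic sphere*
and the rim is an exactly planar, evenly sampled circle; the truth
record carries the closed forms (A = 2πRh, V = πh²(R − h/3),
L_max = 2R when the cap is taller than a hemisphere, else the base
diameter, etc.). At the standard phantom (d = 5 mm, h = 4 mm, 0.2 mm
edges, ~1800 vertices) the measured area and volume are 0.11 % and
0.21 % below the closed forms — pure chord-deficit discretization
error, quadratic in edge length. `make_ellipsoid_cap` scales a
unit-sphere cap anisotropically; its volume truth is closed-form, its
area truth midpoint-rule quadrature (tagged numeric).

`simulate_cohort` models inter-group reconstruction variability with
four seeded mechanisms per group:

1. global scale factor ~ Normal(1, `scale_sd`) — over/under-segmentation;
2. iid vertex displacement along normals ~ Normal(0, `normal_noise_sd`)
   — surface roughness from voxelization and marching;
3. Taubin-style two-step (λ = 0.5, μ = −0.53) uniform-Laplacian
   smoothing for a per-group iteration count drawn from a range —
   different post-processing pipelines;
4. neck-plane tilt ~ |Normal(0, `neck_tilt_sd`°)| and offset
   ~ Normal(0, `neck_offset_sd` mm) with the boundary re-cut by plane
   slicing — different sac/vessel separation. The cut plane is always
   raised just above the previous rim so the re-cut dome keeps exactly
   one boundary loop.

Defaults (25 groups, scale 5 %, noise 0.05 mm, 0–10 smoothing
iterations, 3° tilt, 0.1 mm offset) are chosen as a plausible rendering
of multi-group variability at ~0.3 mm imaging resolution: 5 % scale SD
alone puts the relative uncertainty of a 1D size parameter near 10 %
and, with the other mechanisms added, heights land in the low-teens
percent range reported for real multi-group reconstructions. The model
reproduces the structural findings exactly where they are structural:
under pure scale noise relative uncertainties of 1D/2D/3D size
parameters scale as 1:2:3 (to first order: the 68.3 % range of s, s²,
s³ for s ~ Normal(1, σ)), dimensionless indices are exactly invariant,
and neck-placement noise on a bottlenecked (overhanging) dome inflates
neck-parameter uncertainty ≥ 2× above the height's.

What the generator does **not** emulate: the actual imaging chain
(voxelization at a fixed grid, intensity thresholds, kernel choices),
spatially correlated segmentation error, operator-specific systematic
bias, or branch-vessel inclusion changing neck topology. Passing the
cohort tests therefore shows the statistics and the propagation
machinery are right, not that real inter-group uncertainty has these
magnitudes — the published magnitudes for real cohorts (e.g. curvature
SDs with >100 % relative uncertainty) reflect mechanisms this model
deliberately omits, and no attempt is made to reproduce those specific
values without the real meshes.

## Numerical choices

* Geometric predicate tolerance 1e-9 mm (vertex merge, sphere
  containment, orientation checks); exact arithmetic is not used.
* Percentile positions clamped to [1, n]; all randomness flows through
  one `numpy` Generator per call, seeded, so every cohort and fixture
  is bit-reproducible.
* Slice ties in `H_b` break to the lowest slice; Welzl's point order is
  an internal fixed-seed shuffle (the minimal sphere is unique, so the
  result is order-independent).
* The size-metric record verifies its dimensional inequalities
  (H ≤ H_max ≤ L_max, V ≤ V_CH ≤ V_MBS, A_CH ≤ A_MBS, A ≤ A_closed …)
  on every assembly and raises naming the violated inequality, with a
  1e-6 slack absorbing discretization.

Problem sizes in the shipped tests and in `scripts/acceptance.py` are
chosen to exercise every code path at analytic accuracy on a single
CPU in under a minute per test group: phantom meshes of 1–3k vertices,
cohorts of 20–200 reconstructions, oracle comparisons at n ≤ 30.

## Known limitations

* The neck cap fan can fold for strongly non-planar, non-star-shaped
  neck loops; this is warned about, not repaired.
* `D_neck,equiv = 4A/P` is the textbook hydraulic diameter. Published
  multi-group tables in this area contain at least one internally
  inconsistent value for this parameter (an equivalent diameter larger
  than the maximum diameter, impossible for a planar region), which a
  faithful 4A/P implementation will not reproduce.
* Sub-triangle extremal search is not performed: maxima over the
  surface are maxima over vertices, adequate at ≤ 0.2 mm resolution
  but a systematic lower bound on `L_max`/`D_max` for coarse meshes.
* Curvature near sharp blebs is resolution-limited like any discrete
  operator; GSD/HGC on under-resolved features are unstable by nature,
  which is precisely the uncertainty phenomenon the cohort statistics
  are built to expose.
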