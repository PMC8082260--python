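# Methods

## Reconstruction model

The reconstruction treats a structure as a closed tube.  Known contours
(the sparse delineations) are stacks of closed planar polylines along one
slicing axis; after preparation all contours share a point count p, are
oriented counter-clockwise viewed along the +axis, and have start points
aligned by the cyclic shift minimizing the sum of squared distances between
corresponding points of consecutive contours (exhaustive over all p shifts
— exact and cheap for p ≤ 256; a twisted correspondence would otherwise
brace the tube with crossing edges).

The tube mesh interleaves free intermediate rings between the constrained
known rings (initial positions by linear interpolation of corresponding
points; initialization is irrelevant because the system is solved exactly)
and closes each end with a triangle fan to a single free apex vertex.  The
surface is triangulated (each quad of consecutive rings split into two
triangles) for output, but the operator lives on the *connectivity graph*:
each ring vertex is adjacent to its two ring neighbours and the
corresponding vertex of the rings above and below (4 neighbours), each apex
to every vertex of its end ring.  On that graph the umbrella Laplacian
L = I − D⁻¹A is purely combinatorial — geometry never enters L, which is
what makes the solve exactly equivariant under rigid motions and uniform
scaling of the input contours.

Free coordinates solve (L²)_ff x_f = −(L²)_fc x_c independently for x, y, z
(one sparse LU factorization, three right-hand sides).  L² is the matrix
square of the row-normalized operator, matching the Σₘ L²ₙₘ xₘ = 0 form;
since L is row-normalized it is not symmetric wherever the apex degree p
differs from 4, so L² is used rather than LᵀL.  For tubes whose every
vertex has degree 4 the two coincide and the solution is the exact
minimizer of ‖Lx‖² subject to the constraints (verified in the tests).
Constraints are imposed by hard elimination — constrained rows are removed
from the system, so delineated points are reproduced bit-for-bit, never
approximated by a penalty.  The residual maxₙ |Σₘ L²ₙₘ xₘ| over free rows
is checked after every solve against 1e-8 × the coordinate scale; a
violation raises rather than returning a degraded surface.

### Parameters

| parameter        | default | meaning |
|------------------|---------|---------|
| `n_contours`     | 10      | outlined contours extracted at regular intervals |
| `n_points`       | 64      | points per contour after arc-length resampling |
| `n_intermediate` | 1       | free rings per gap between known contours |
| `axis`           | z (axial) | slicing axis |
| `end_margin_mm`  | 0.5     | distance of the outermost contour planes from the surface ends |

Contour placement spans the full axial extent minus `end_margin_mm` at each
end; with the default half-voxel margin the outermost contours sit just
inside the surface, bounding the cap bias (see below).  Plane positions are
an arithmetic sequence — regular intervals being the point of the
reduced-workload protocol.

`n_intermediate` defaults to **1** after an explicit design comparison.  An
automatic mode (ring spacing ≤ the axial voxel spacing, available as
`n_intermediate=None`) was evaluated and rejected as the default: the
radius drop from the last ring to the cap apex is a sharp feature in the
graph-index domain, and the bi-Laplacian responds to it the way splines
respond to steep data — by overshooting.  The more free rings a gap has,
the more room that oscillation has to express; on the standard phantom
cohort the automatic mode bulged cross-sections near the caps (up to
+100 mm² on bent tubes), inflated reconstructed volumes and *lowered* the
mean Jaccard index (0.974 vs 0.980).  One intermediate ring per gap is both
the fastest and the most faithful setting; the number of intermediate
contours is exposed because it is genuinely consequential.

Plane orientation is axial by default (delineation protocols for deep grey
matter draw on axial slices); the slicing axis is configurable.

### Caps

Each end is closed by a triangle fan to one apex solved as a free vertex,
letting the fairing place the pole.  Empirically the solved apex sits close
to the end-ring plane (the umbrella weighting ties a degree-p apex to the
ring mean), so caps are nearly flat: volume beyond the outermost contours
is mostly truncated.  This is the mechanism behind the reconstruction's
volume bias: the deeper inside the structure the outermost contours are
placed, the more apical volume is cut off.  On ellipsoid phantoms the
faired-mesh volume deficit grows monotonically as the end margin moves from
0.5 to 1.5 to 2.5 voxels, and on the standard cohort the Bland–Altman mean
difference (reconstructed − reference) is negative with p < 0.001 —
systematic underestimation, concentrated at the caps.

## Rasterization

Masks and surfaces exchange through two exact, deterministic conversions:
marching cubes at iso-level 0.5 (masks → meshes, world-mm vertices,
watertightness enforced) and per-slice scan conversion (meshes → masks): a
voxel is set iff its center lies inside the mesh, decided by cutting the
mesh with the plane through each slice's voxel centers (exact
triangle/plane section) and testing grid points against the resulting loops
with even-odd parity.  Slice planes are perturbed by 1e-6 × spacing so
planes coinciding with contour rings do not produce degenerate coplanar
cuts; the shift is orders of magnitude below discretization error.  Note
that the voxel-center rule applied to a ringed, piecewise-linear tube
counts slightly differently than to a smooth surface of equal volume
(section area is sampled mid-slice, and concave kinks between rings bias
the sample upward); this is a property of the rule, not of the
implementation, and is small next to the cap effects at the default ring
setting.

## Phantoms and simulated raters

The phantom generator emulates the *geometry regime* of deep grey matter
structures — smooth, compact, single-component shapes of 3.5–8 mL on a 1 mm
isotropic grid — with three families whose volumes have closed forms, so a
target volume is hit analytically and the discretized masks can be audited
against the formulas (voxel volume within 2% of analytic for ≥ 4 mL
shapes):

- **ellipsoid** (V = 4/3 π a b c), mild random anisotropy, elongated along
  the slice axis;
- **superellipsoid** (exponent 2.5–4; V via Gamma functions) — flatter
  poles, testing cap truncation;
- **bent tube** (circular-arc centerline, hemispherical caps; V by Pappus)
  — a curved medial axis, the closest analogue to the caudate's arc.

Shape centers are jittered by a uniform sub-voxel offset relative to the
grid: real structures sit at arbitrary positions relative to the scanner
lattice, and exactly grid-aligned symmetric shapes are a degenerate
alignment that produces lattice-coincidence artifacts in voxel-center
counts.

Simulated raters perturb a mask by adding a unit-variance Gaussian-smoothed
random field, scaled by an amplitude in mm, to the signed distance
transform and re-thresholding at zero — spatially coherent boundary
displacement rather than voxel noise.  Defaults (amplitude 0.5–1 mm,
correlation length 3 mm) produce plausible-looking disagreement at the
1 mm-voxel scale but are *not* calibrated to any measured human
inter-rater statistic, and results obtained with them say nothing
quantitative about human raters.  What the phantom suite *does* establish:
the geometric pipeline is exact where it should be exact, its errors sit
where the model predicts (caps, inter-contour gaps), and the agreement
statistics are computed correctly.  What it cannot establish: performance
on real anatomy with thin protrusions (a caudate tail sharper than the
bent tube), multi-component cross-sections, or real rater behaviour.

Experiment drivers mirror a train/test evaluation: a deterministic split of
the cohort, exhaustive grid search of fairing parameters maximizing mean
Jaccard on the training half (ties broken toward fewer contours, then fewer
points — lower delineation workload), evaluation of the winner on the
held-out half, and the Bland–Altman volume-bias contrast.  Per-case
failures in cohort runs are logged and excluded with a count rather than
aborting the batch.  The standard cohort for headline numbers is 24
phantoms (8 per family), volumes uniform over 3.5–8 mL, seed-fixed; it runs
in seconds, so no scaling-down of the published conditions is needed.

## Numerical and degenerate-case choices

- Sparse direct LU on the reduced system (≲ 10⁴ unknowns); singularity is
  reported with graph diagnostics instead of silently regularized.
- Contour resampling is chord-based arc-length interpolation; it preserves
  perimeter within 1% at ≥ 32 points and area within 2% on convex contours,
  and is only asymptotically idempotent, so re-preparing an
  already-prepared set is short-circuited by contract.
- Multi-loop cross-sections keep the largest-area loop with a warning (the
  tube topology admits one contour per level).
- Overlap of two empty masks is an error, not 1.0 — an undefined ratio
  surfacing early beats silent cohort corruption.
- Bland–Altman with zero-variance differences reports a degenerate flag and
  NaN p-value instead of a fabricated test statistic.
- ICC is the single-measure absolute-agreement point estimate; "mixed" vs
  "random" rater models differ only in inference, which is not computed.
- Any nonzero label binarizes to 1 with a warning (structures are
  delineated one at a time); masks are reoriented on read so the third
  array axis is axial.

## Known limitations

- One tube per structure: branching topologies and multi-component
  cross-sections are out of scope.
- The cap model (fan to a free apex) truncates apical volume by
  construction; structures with substantial volume beyond the outermost
  contour planes are underestimated.
- The rater-noise model is a stand-in, uncalibrated to human variability.
- Cross-sectional (3D) only; longitudinal fairing is not implemented.
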