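# Methods

## The measurement

One subject's input is a pair of lower-leg surfaces (tibia and fibula per
side, STL in millimetres, or a CT volume segmented by this package). All
geometry lives in a right-handed patient frame: X left→right, Y front→back
(anterior→posterior), Z feet→head. DICOM LPS input has its X axis negated by
the volume loaders (DICOM's own +X points toward the patient's *left*, the
opposite sense of the frame the clinical angle readings are defined in; the
flip is explicit and tagged on the volume). NIfTI RAS input has Y negated.

The analysis of `analyze_pair` proceeds in five steps:

1. **Mirror.** The left leg is reflected about a sagittal plane
   `x = const`. The offset is immaterial — the proximal registration absorbs
   any translation — and defaults to the mid-plane of the pair's joint
   bounding box. Face winding is flipped so closed meshes keep positive
   signed volume; the mirror is an exact involution.
2. **Pre-alignment and segmentation into bands.** A coarse principal-axis
   alignment brings the mirrored leg onto the right leg, and both legs are
   cut into a proximal band (default 30% of the length from the knee end:
   plateau, fibular head, proximal diaphysis) and a distal band (default
   30% from the ankle end: plafond, malleoli, distal diaphysis) along the
   **right** leg's long axis. The long axis is the first principal axis of
   the area-weighted face centroids — an exact surface moment, so the cut is
   rigid- and mirror-equivariant and a symmetric pair is cut into exact
   partner segments whatever the scanner pose. Orientation (which end is
   proximal) is decided once, on the clean right leg, by the fatter-end rule
   (the knee end carries the plateau and fibular head); for an upright leg
   this reduces to the feet-to-head +Z convention. Cutting both legs by one
   axis decided on the reference leg avoids a failure mode where a large
   deformity tilts the deformed leg's own axis enough to flip the decision.
3. **Proximal (stationary) registration.** The mirrored-left proximal band
   is registered onto the right proximal band and the resulting transform is
   applied to the whole mirrored leg. If this registration needs a rotation
   above 90° *and* fails its distance gate, the run aborts with an
   orientation error — the signature of an unmirrored left leg (a chirality
   mismatch can never fit well). Rotation alone is not grounds to abort: a
   legitimately posed pair can need a large proximal rotation while fitting
   perfectly.
4. **Distal (moving) registration.** The pre-aligned mirrored-left distal
   band is registered onto the right distal band. Its residual transform is
   the deformity.
5. **Decomposition.** Rotations are fixed-axis X·Y·Z Euler angles of the
   residual rotation, sign-flipped from the right-hand rule (see below);
   translation is the displacement of the distal band's centre of mass
   under the residual transform, which is independent of the coordinate
   origin. Both registrations' fit qualities are attached, and the report
   is flagged unreliable if either gate fails.

### Sign convention

Angles are positive for rotations that appear clockwise to an observer
looking along the positive axis *from its tip toward the origin* —
numerically the negation of the right-hand-rule angle. The underlying
clinical phrase ("clockwise positive when looking along the positive axis")
is genuinely ambiguous about where the observer stands; this package fixes
the tip-toward-origin reading, applies it identically in the pipeline, the
phantom truth tables and the statistics, and documents it here so results
are reproducible. At the magnitudes relevant to leg symmetry (a few
degrees) the X·Y·Z ordering is immaterial: re-decomposing rotations
composed in any of the six axis orders moves the recovered angles by under
0.05° for inputs ≤ 1.5°.

A consequence of the mirror construction worth knowing: exchanging which
leg is "right" conjugates the deformity by the sagittal mirror, so ROTX,
COMY and COMZ change sign while ROTY, ROTZ and COMX keep theirs. Torsion
("the left is externally rotated relative to the right") is a
chirality-adjusted statement and survives the swap with its sign intact.

## Registration

Correspondences are exact closest points on the fixed *surface* (not a
second point cloud): a KD-tree over triangle centroids prunes candidates,
the region-classification closest-point-on-triangle computation finishes
the query, and an answer is only accepted once no unexamined triangle could
be closer (certified by the centroid distance minus the largest
centroid-to-vertex radius, with a widening ball query for the stragglers).
A cloud-to-cloud mode is available for comparison via the sampling
utilities, but point-to-surface is the default because it removes
sampling-density bias from the metric.

The solver is trimmed ICP: area-uniform points sampled once on the moving
surface; per iteration, closest points on the fixed surface, the worst
`trim_fraction` (default 10%) of correspondences discarded, and the full
transform re-estimated by the Kabsch/SVD least-squares fit (determinant
forced to +1, so never a reflection). Trimming gives localized artifacts —
implants, streaks, segmentation warts — limited influence: welding a
bump of ~5% extra area onto a surface moves the recovered transform by
under 0.2°.

Two refinements matter numerically:

* **Coarse-to-fine.** The linear-rate early iterations run on a subsample
  (1/8 of the points, minimum 500), then the full set takes over. Same
  optimum, several times fewer expensive iterations.
* **Point-to-plane polish.** Near-tubular surfaces can slide tangentially
  along themselves almost freely; point-to-point updates then shrink the
  objective by a tiny near-constant factor per step and stall 0.1–0.2 mm
  short of the optimum — enough to violate the package's own accuracy
  targets. After the Kabsch loop converges (or stalls: three consecutive
  relative improvements below 3% hand over early), a Gauss–Newton
  point-to-plane stage (≤12 iterations, residuals along the fixed surface's
  face normals, exact re-orthonormalization each step) lets the
  landmark-bearing regions snap the remaining tangential offset. On
  noiseless phantoms this takes the null-case and recovery residuals from
  ~0.1 to ~1e-13.

The initializer matches exact area-weighted surface centroids and principal
axes; the four proper-rotation sign candidates are scored by mean
nearest-neighbour distance on 2000-point samples, and nearly isotropic
shapes (relative eigenvalue spread < 5%) fall back to centroid-only
alignment. Identical meshes therefore initialize exactly at the identity.
The distal stage also starts from this initializer rather than the
identity: after proximal alignment the segments are close, but a pure
axial shift slides a tube along itself and an identity start can strand
ICP in that shallow valley.

**Fit gate.** Quality is the mean exact surface distance of `fit_points`
(default 10,000) *fresh* samples — drawn from a seed stream distinct from
the optimized points, so the reported metric is not the optimized quantity
— gated at 0.5 mm. Convergence is an absolute trimmed-mean improvement
below `convergence_tol` (default 1e-4 mm) or a settled polish step;
non-convergence is reported in the result, never raised.

Defaults (100,000 measurement points, 10,000 fit points, 0.5 mm gate)
follow the clinical protocol; tests and the acceptance script run 4,000 /
1,500 points, since on noiseless phantoms accuracy is set by convergence,
not point count, and the suite then completes in minutes.

## Segmentation

A stand-in for the proprietary two-parameter workflow of the commercial
software, built from its published description (a click per bone plus
Hounsfield thresholding): 26-connected region growing over voxels at or
above a threshold (default 250 HU — bracketing cortical and dense
trabecular bone; the clinical software's internal value is unpublished).
When one thresholded component holds seeds with different labels, voxels go
to the nearest seed in millimetres (anisotropy-aware; ties to the
lexicographically lower label), so masks are always disjoint. Regions
touching the volume border are flagged as possibly truncated. An optional
3³ majority filter (off by default, recorded when used) suppresses
partial-volume speckle. Meshing is marching cubes on the zero-padded mask
at level 0.5, winding fixed to positive volume. Equivalence with the
commercial implementation is *not* claimed; what is validated is closure:
rasterize → segment → mesh → register against the source phantom recovers
the identity to under 0.05° and 0.15 mm at 1.25 mm voxel pitch (the test
threshold is 0.5°/0.5 mm).

## The synthetic phantom

The generator aims at geometric sufficiency, not anatomical realism: a
tapered, waisted *elliptical* tibial shaft whose cross-section twists ~15°
along its length (so torsion is observable on the diaphysis), a plateau
bulb, a plafond bulb and a medial malleolus; a slender fibula with head and
lateral malleolus, offset laterally. The left leg is the exact mirror of
the right *before* deformity injection — the mirror-null case is exact by
construction. Deformities rigidly transform a distal (or proximal) band of
the left leg about the band's own centroid, cut sharply (default) or
blended over a 20 mm smoothstep band; the injected band (default 40% of
the length) strictly contains the analysis band (30%), so sharp injections
admit exact recovery. Surface noise displaces vertices independently along
vertex normals. Everything is seeded; regenerating with the same spec is
hash-identical within a session.

Ground truth for recovery tests is computed analytically: an injected
left-frame motion `A` appears to the analysis as its sagittal-mirror
conjugate `D = M A M`, the distal registration recovers `D⁻¹`, and the COM
displacement is `c₀ − D(c₀)` with `c₀` the exact centroid of the clean
right distal band. For large rotations the measured COM picks up ~1 mm of
definition-dependence (the deformed leg's band quantiles shift slightly),
which is why recovery checks compare the injected parameter and the
rotation cross-talk, where agreement is exact.

Cohort generation draws per-axis distal rotations and translations from
normal distributions (defaults 1.5° / 1.5 mm — the order of healthy
side-to-side asymmetry) and returns the matching truth table.

What the phantom does **not** emulate: real cortical shape variation,
joint articulation, imaging physics (beam hardening, contrast, noise
texture), or metal artifacts. Passing tests therefore demonstrate the
correctness of the *measurement machinery* under known geometry, not
clinical accuracy on patient CTs.

The rasterizer assigns 1200 HU inside any closed bone component (inside
tests by vertical ray-crossing parity with jittered columns, per component
so overlapping closed parts union correctly), 40 HU inside an inflated
convex soft-tissue hull, −1000 HU elsewhere.

## Cohort statistics

Per parameter: mean, median, sample SD (n−1), SEM, and the 95% CI of the
mean using Student t with n−1 degrees of freedom (t₀.₉₇₅,₉ = 2.2622 at
n = 10) — reconstructing the published cohort's CIs from its per-subject
values matches the printed bounds to ±0.001 under t and visibly not under
z, which validated the choice. A parameter is flagged when its CI strictly
excludes zero (a degenerate [0, 0] interval still contains it). An
RMS-about-zero column is included for completeness. Normality: Shapiro–Wilk
(Royston's formulation via scipy) and the Lilliefors-corrected KS test
(statsmodels table p-values), with p reported as "≥0.2" beyond the table
range, matching how SPSS prints it.

The packaged 10-subject fixture is transcribed from the published
per-subject table; its loader recomputes every column mean at load time and
refuses to return data straying more than 0.01 from the published means.
One transcription ambiguity (a stray minus sign on one subject's COMX) was
resolved by that self-check. Two printed summary values (the ROTZ mean and
median) differ from recomputation by ~0.005 and ~0.012 respectively — the
published summary was evidently computed from unrounded data — and are
documented rather than "corrected" on either side.

## Numerical choices and degenerate inputs

* Rigid transforms are validated to 1e-6 orthonormality and re-snapped to
  the nearest exact rotation by SVD beyond 1e-9, so long compositions stay
  rigid. Reflections (det −1) are rejected.
* Euler decomposition at gimbal lock (|ROTY| = 90° within ~1e-6°) sets
  ROTX := 0 by convention and flags the result; the flagged angles still
  rebuild the rotation exactly.
* Kabsch requires ≥3 non-collinear pairs (second singular value test).
* Zero-area meshes cannot be sampled; empty masks cannot be meshed; seeds
  below the HU threshold name the offending seed; a constant sample has an
  undefined normality test (surfaced per column, not fatal).
* Mesh cutting clips straddling triangles exactly at the plane and leaves
  the rim open — registration samples surfaces, so closure is not needed
  there; rasterization, which does need closure, validates watertightness.
* Angle ties in the nearest-seed voxel partition go to the
  lexicographically lower label; sampling, ICP, phantom noise and cohort
  draws all consume named, purpose-separated seed streams.

## Problem sizes in the shipped tests

The suite and acceptance script use phantom meshes of ~15k faces per leg,
4,000/1,500 registration points, a 120 mm leg at 1.25 mm voxel pitch for
the segmentation closure, 20 random poses for the mirror-null check,
rotation grids of 2–20° × three axes and translations of 1–10 mm (clean
and at 0.3 mm noise), and 2000 simulated cohorts for CI calibration —
sizes chosen so the whole suite validates every claim in a few minutes
while leaving the library defaults at the clinical protocol values.

## Known limitations

* Segment "levels" are fractions of leg length, not anatomical landmarks;
  the published technique does not state its cut levels either, so
  cross-package comparability of COM values at large deformity is limited.
* COM is a surface (not volumetric) centroid estimated from sampled
  points, matching the described measurement; it converges to the exact
  area-weighted centroid but is not the mass centroid of the bone.
* The pipeline assumes whole-leg surfaces of reasonable quality; it fixes
  winding but does not repair holes or self-intersections.
* Not an intra-operative tool; femur/pelvis analysis and fracture-fragment
  tracking are out of scope.
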