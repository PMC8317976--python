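# Methods

`carmplan` models the geometry that lets a mobile C-arm fluoroscope act as a
co-registered "imaging observer" in a spatially-aware operating room: a
visual tracker rigidly mounted on the scanner reports poses in a shared OR
frame, a one-time hand-eye calibration links those poses to the X-ray source,
and from there every 2D image pixel has a known 3D ray. On top of that sit
two intra-operative planning procedures (staged virtual-tool alignment and
two-view ray reconstruction), acetabular cup planning against the anterior
pelvic plane, and the outcome metrics and statistics used to evaluate such a
system pre-clinically. Everything runs on synthetic scenes; no hardware or
image data is required.

## Conventions

All transforms are SE(3) with column vectors acting on the left; lengths are
millimetres and angles degrees at API boundaries. Unit quaternions are
scalar-first with the canonical sign s >= 0 so solver outputs are unique.
Pixel coordinates have their origin at the top-left of the image, x right,
y down, principal point at the image centre unless overridden.

## Hand-eye calibration (AX = XB)

Corresponding pose streams — the source tracked externally (^IR^T_X) and the
on-gantry tracker localised in the OR frame (^OR^T_H) — are turned into
relative-motion pairs A = T_X(t_j)^-1 T_X(t_i), B = T_H(t_j)^-1 T_H(t_i),
consecutive by default (all index pairs optionally). Rotation and translation
are decoupled:

* **Rotation.** q_A q_X = q_X q_B rearranges, per pair, into a homogeneous
  4x4 block in (s_A - s_B, v_A - v_B, v_A + v_B) acting on q_X; stacking all
  pairs gives M (4N x 4) and q_X is the right singular vector of the smallest
  singular value (min ||M q|| s.t. ||q|| = 1). Because A and B are conjugate
  their scalar parts agree, so canonical quaternion signs on both sides keep
  every block consistent.
* **Translation.** (R_A - I_3) t_X = R_X t_B - t_A stacked over pairs and
  solved by linear least squares; the RMS residual is reported in mm.

Numerical safeguards: pairs rotating less than 5 deg (configurable) are
dropped — they contribute nothing to the rotation system and ill-condition
the translation one; pairs whose A/B rotation angles disagree by more than
2 deg are dropped as inconsistent correspondences; if the ratio of the two
smallest singular values of M is under 10 the motion axes were (nearly)
collinear, the rotation about that common axis is unobservable, and the
result carries a `degenerate` flag; a translation system whose 3x3N stack is
rank-deficient (all motions near pure translation) raises instead of
returning garbage. The geodesic rotation-error metric is computed through
the quaternion (2 atan2(|v|, s)) rather than arccos of the trace, whose
sqrt(eps) floor (~1e-6 deg) would otherwise dominate exact-recovery checks.

`sampling_experiment` repeats calibration on random subsets of a pose pool
(default 100 repetitions per subset size, seeded) and tabulates mean/SD/
median errors against the known ground truth — the standard
accuracy-versus-pose-count picture.

## The flying frustum

One acquisition defines the full pyramid of vision with apex at the source
and base at the detector at focal distance f. The image may be displayed on
a *near* plane at any user-chosen n in [0, f]: coordinates scale by n/f
(diag(n/f, n/f, 1) ahead of the intrinsics) and the interactive image pose
is the source pose translated n along the principal axis — at n = f the
image sits at the detector at detector scale, at n = 0 it collapses onto the
source. n outside [0, f] is a hard error, since the model is only defined
there. The projection uses the inverse of the source pose as its extrinsics
(the world-to-camera map), which is what makes backprojected rays from two
frustums meet at the 3D point they both image; backprojection undoes the
near-plane scaling first, so a pixel annotated at any n yields the same ray.
Default intrinsics are f = 1000 mm, 1024 x 1024 pixels at 0.3 mm/px — a
generic mobile C-arm geometry, all overridable; no distortion model is
applied. Clipping semantics are deliberately absent: the frustum is the full
pyramid, not a graphics-style truncated one.

## Staged virtual-tool alignment

The virtual drill carries its K-wire along local +Z. Free 6-DOF alignment
against two images at once is hard, so the freedom shrinks in stages:

1. **Init + stage 1 (theta, t_x, t_y, t_z).** The tool's local Y axis is
   rotated (minimal rotation) onto the first frustum's viewing direction —
   either the principal axis (the literal reading) or the ray through the
   tool origin (`viewing_ray`, the default). Then theta spins the tool about
   Y and the translations place it until the wire's projection lies on the
   first target line.
2. **Stage 2 (phi, psi, t_y, t_z).** With Y along the viewing ray through
   the origin, each remaining DOF is image-1 neutral: phi rotates the wire
   inside the plane spanned by the ray and the wire, psi spins the tool
   about its own wire, t_y slides along the ray and t_z along the wire.
   These align the second view without disturbing the first.
3. **Stage 3 (psi, t_z).** Spin about and slide along the wire: the wire's
   3D line is invariant, so nothing changes in any view.

The closed-form stage-2 matrix combines the angles as R_z(psi) R_x(phi).
Applied in one shot with both angles nonzero that order tips the wire out of
the viewing plane (the offending term is sin psi sin phi), so the alignment
*application* path applies them intrinsically X-then-Z (R_x(phi) R_z(psi)):
the same two interactive DOF, with psi always acting about the wire itself,
which preserves image-1 alignment exactly for every parameter combination.
In `principal_axis` mode the neutrality is only approximate (exact solely on
the principal ray); the deviation is measured, not asserted away.

`auto_align` automates the interactive user: stage 1 re-anchors the tool
origin on the backprojected ray of the first target's entry pixel (at the
depth of the initial origin, so an already-aligned pose is reproduced
idempotently) and solves theta by a 15-degree grid plus Levenberg-Marquardt;
stage 2 solves (phi, t_y) the same way against the second view, picking of
the two line-preserving orientations the one pointing entry-to-exit; stage 3
slides t_z so the projected wire covers the targets longitudinally. Because
the first target's entry ray contains the true entry point and stage-2's
in-plane family covers every line in the first backprojection plane through
that ray, noiseless two-view targets are recovered exactly (the acceptance
suite checks 0.1 mm / 0.1 deg; the solver lands at machine precision).
Alignment quality is an RMS of sampled point-to-infinite-target-line
distances (33 samples by default) plus a longitudinal overlap fraction;
the stage-1 preservation tolerance defaults to 0.5 px.

## Two-view ray reconstruction

An annotated pixel backprojects to the ray (c_i, u_i). A landmark seen in
N >= 2 views is the least-squares closest point to its rays, solved through
the normal equations sum_i (I - u_i u_i^T) x = sum_i (I - u_i u_i^T) c_i;
the reported residual is the RMS perpendicular distance to the rays. The
system is declared degenerate (error raised) when the smallest eigenvalue of
the normal matrix falls below 1e-6 of the largest — mutually parallel rays.
For a drilling trajectory, entry and exit pixels in one view span a plane
with normal u_1 x u_2; the line is the intersection of the two views' planes,
direction (u_1i x u_2i) x (u_1j x u_2j), anchored at the triangulated entry
point and oriented entry-to-exit. N = 2 reproduces the classical midpoint of
the common perpendicular exactly; N > 2 is a natural extension of the same
normal equations.

## Cup planning against the anterior pelvic plane

The APP frame is built from the two ASIS points and the pubic symphysis:
transverse = right-to-left ASIS, longitudinal = in-plane caudal-to-cranial
(the pubis-to-mid-ASIS direction orthogonalised against transverse), normal
= transverse x longitudinal, which points anterior for anatomically labelled
landmarks. A configurable posterior reference (default: the acetabulum
centre) guards the orientation; if it falls anterior, the normal and
longitudinal flip with a warning (right-handedness preserved), signalling
inverted labels. The angle convention is radiographic, matching the
in-plane/out-of-plane split: anteversion = arcsin(axis . normal), abduction
= atan2 of the in-plane projection against the longitudinal axis. The
forward map `desired_cup_axis` is the exact inverse on (0, 90)^2; an axis
normal to the APP makes abduction undefined and is reported as 0 with a
warning. Whether the original measurements were radiographic or operative is
not knowable from the outcome tables; only this convention is claimed, and
it lives in one code location.

## Synthetic scenes

The generator emulates the study conditions, not real fluoroscopy:

* **Tube phantom** — a ~10 mm bone canal (wire 2.8 mm), default centerline
  oblique to all axes so no standard view looks down the canal.
* **Pelvis phantom** — a compact (roughly half adult scale) landmark set
  sized to stay inside the default field of view across oblique views, with
  the acetabulum posterior to the APP.
* **Orbits** — source poses on a circle (default radius 600 mm) about an
  isocenter, principal axes through the isocenter; view separations of
  30 deg or more are used throughout.
* **Pose noise** — axis-angle rotation noise (uniform random axis, normal
  magnitude) right-multiplied onto the pose, plus isotropic normal
  translation noise; magnitudes default to the low-degree / few-mm scale of
  inside-out SLAM tracking. Annotation noise is isotropic Gaussian in px.
* **Calibration datasets** — 120 pose pairs by default; tracker poses are
  constructed from a fixed loop-closure transform so they are exactly
  consistent with the ground-truth X before noise.
* **Executed insertions** — a planned trajectory perturbed by a tilt about a
  random perpendicular axis and a perpendicular entry offset.

What this does not model: image formation (attenuation, scatter, intensifier
distortion), soft tissue, patient motion between views, SLAM drift
structure (noise is i.i.d. per pose), or human interaction. Passing tests
therefore demonstrate geometric correctness and noise propagation of the
algorithms, not clinical performance.

## Outcome metrics and statistics

`wire_error` intersects the executed wire with the planes of the tube's
entry and exit faces and averages the two distances to the face centres —
the error definition used for tubular-phantom drilling studies (a wire
parallel to a face plane has no intersection and raises). Study summaries
expose both SD conventions because the published numbers mix them: prose
"mean +/- SD" uses the population SD (n denominator), tabulated
parenthesised SDs the sample SD (n - 1). The 95% CI defaults to
mean +/- 1.96 sample SD / sqrt(n), which reproduces the published intervals;
a Student-t CI is available. The two-sample t-test is implemented in closed
form with pooled (default) and Welch variants; pooled reproduces the
published wire-error comparison (p = 0.93). `reproduce_study_tables` audits
every published summary against the packaged raw tables and flags the four
entries that do not reproduce (an execution-time mean/SD pair whose
published value is consistent with the published combined time but not with
the published per-participant row; a cup-placement dose SD printed equal to
its mean; a time SD rounded low) rather than silently failing or silently
passing.

## Known limitations

* Poses are consumed as given; SLAM itself, image rendering and any UI are
  out of scope.
* The staged aligner assumes targets are straight segments; curved implants
  would need the generic 6-DOF projection route.
* Degeneracy thresholds (1e-6 eigenvalue ratio, singular-value gap 10, 5 deg
  minimum pair rotation) are pragmatic defaults, not estimated from data.
* Problem sizes in the test and acceptance runs (120-pose pools, 100
  repetitions per subset size, two-view scenes) match the study's scale and
  keep the whole suite in the minutes range on one CPU.
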