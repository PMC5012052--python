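# Methods

## Geometric model

Each vertebra (C1, C2) carries an anatomical coordinate frame built from
three ROI points placed in its sagittal (symmetry) plane: an origin `O`
and two points `A`, `B` on the in-plane reference axis.  For C2 the
reference line is the ventral border of the vertebral foramen (a
craniocaudal axis); for C1 it is derived from the cranial border of the
dorsal and ventral arches.  The frame is

* `X = unit(A − B)` — the published definitions fix the reference *line*
  but not its sense, so the package fixes the convention that `A` is
  placed cranial to `B` and X points cranially;
* `Y = unit((A − O) × (B − O))` — the normal of the landmark plane
  (mediolateral).  No sign convention for Y is published either; the
  cross-product orientation above is deterministic given the documented
  landmark placement and makes the triad right-handed with
  `Z = X × Y` in the sagittal plane (ventrodorsal).

Landmarks with triangle area below 1e-6 mm² are rejected as collinear —
far below operator placement precision (~0.3 mm), so any real triplet
passes and genuinely degenerate input fails loudly.

An implant is the segment from insertion `I` (on the ventral bone
surface) to exit `E`.  Its direction is re-expressed in the anatomical
frame by a change of basis, `v = R (E − I)` with the frame axes as the
rows of `R`, and reported as projected angles:

```
sagittal  = atan2(z, x)
dorsal    = atan2(y, x)
transverse = atan2(y, z)
```

with `v = (x, y, z)` = (craniocaudal, mediolateral, ventrodorsal).  The
two-argument arctangent makes each angle the signed angle between the
projection of `v` onto the named plane and the plane's reference axis,
verified in the test suite against an independent projection oracle
(explicit plane projection + normalized dot product).  The transverse
angle uses the ventrodorsal axis as its zero reference.  Oblique sites
report the (sagittal, dorsal) pair as their 3D coordinates; strictly
sagittal sites are defined by the sagittal angle alone.  Transarticular
C1–C2 implants project in the C1 frame.

Safety margins: four points `S1..S4`, grouped as two pairs lying in two
orthogonal planes through the implant axis (a >5° deviation from
orthogonality triggers a warning, not an error).  The safety angle of
one point is

```
SafA = α − arcsin(r / |S − I|)
```

where `α` is the angle between `E − I` and `S − I` and `r` the implant
radius (default 0.75 mm — half the 1.5 mm implant diameter used in the
validation).  This is the angle through which the implant axis can pivot
about `I` before touching the circle of radius `r` about `S`; the test
suite checks it against a rotating-ray tangency oracle solved by root
finding.  Negative SafA (corridor narrower than the implant) is returned
unclamped and flagged.  Corridor width in each safety plane is the sum
of the two perpendicular point-to-axis distances when the pair flanks
the axis; a same-side pair yields a flagged non-positive value.  The
radius enters SafA only, not the width.

Centered axes of the simplified corridor shapes: pyramid — apex to base
centroid; prism — end-face centroid to end-face centroid;
hemi-ellipsoid — principal (longest) semi-axis of an algebraic
least-squares ellipsoid fit (general quadric, eigendecomposition),
anchored at the base-plane centroid.  Implant endpoints on an axis are
the axis points closest to the ventral-surface and far-boundary sample
sets.  The published per-site construction details are not available in
machine-readable form, so the site catalog (13 sites: 2 lateral mass,
1 ventral arch, 2 transarticular, 2 cranial articular, 2 pedicular,
3 caudal body, with the shape kind and projection pair per site) pairs
with these generic constructors; the shape assignment per site is a
package convention.

## Agreement statistics

Lin's concordance correlation coefficient uses population (1/n) moments
(the original formulation); a sample-moment variant is exposed.
Bland–Altman differences are `test − reference`; bias CI uses
`t(0.975, n−1)`; the paired location test is the two-sided paired
t-test.

The "95% tolerance interval" is implemented as the two-sided
normal-theory tolerance interval with 95% coverage at 95% confidence,
`bias ± k·SD` with Howe's approximation
`k = z₀.₉₇₅ √((n−1)(1+1/n)/χ²₀.₀₅,ₙ₋₁)`.  This choice was fixed by
recomputing the packaged validation table under the candidate
procedures: the plain `±1.96·SD` limits and the single-future-observation
prediction factor `t·√(1+1/n)` both undershoot the published limits,
while the 95%/95% factor reproduces them to the printed precision
(k = 2.2395 at n = 96, 2.1468 at n = 192).  Both alternatives remain
available via `tolerance_method=`.

Absolute-error summaries report mean ± sample SD of |test − reference|
per group; a population-SD option exists.  No multiple-testing
correction is applied (per-comparison p-values are reported).

In repeat-vs-repeat and observer-vs-observer comparisons the sign of the
bias (and the asymmetry of the tolerance limits) depends on which series
is subtracted from which; this package always uses `test − reference`
with the first-listed series as reference.

The landmark-reproducibility analysis takes one quadruple of recomputed
ProjA values per (case, site, angle) — 2 observers × 2 repeats — uses
their mean as the per-item gold standard, and compares single values,
two-observer means and two-repeat means against it, with subgroup
analyses by projection plane and by vertebral frame.

## Synthetic scenes

No public imaging data accompanies the method, so scenes are built by
inverse construction: implant directions from prescribed (sagittal,
dorsal) angle pairs via `d ∝ (1, tan θ_dor, tan θ_sag)`, exit points at
`I + L·d`, and safety points at ±3 mm perpendicular offsets in two
orthogonal planes through the axis — at 75% of the corridor length for
sagittal canal-directed sites (the data-collection rule for such
implants), mid-axis otherwise.  Defaults: 12 cases, 10 mm implants,
0.75 mm radius, per-case anatomical scale jitter ±10%, landmark triplets
on a canonical ~30 mm (Toy-breed scale) template with reference-line
spans of ~16 mm (C1) and ~22 mm (C2) — the template is an arbitrary
stand-in since no coordinates are published.  Each case receives a
uniformly random rigid pose (quaternion rotations, ±100 mm
translations); since every reported quantity is a rigid invariant this
exercises the invariance without affecting ground truth.

Operator landmark variability is modelled as isotropic Gaussian
displacement of the O/A/B points, default SD 0.3125 mm (half a typical
CT slice thickness, the stated bound on placement error); implant points
are left untouched.  The landmark-error experiment recomputes each
implant's reported ProjA under 4 such replicate landmark sets and feeds
the quadruples to the reproducibility analysis.

What the generator does **not** emulate: real bone-surface geometry and
site-specific corridor shapes, anisotropic (in-plane vs through-plane)
operator error, observer-specific bias, or atlantoaxial subluxation.
Passing tests therefore demonstrate the correctness of the geometry and
statistics and the qualitative error structure (intervals collapse as
noise → 0, widen monotonically with noise, two-observer means beat
single values), not the numerical error magnitudes of any real cohort —
with isotropic noise the simulated single-value tolerance intervals come
out somewhat wider than those reported from real repeated landmark
placements.

## Numerical choices and limitations

* Angles are computed with `atan2` (full signed range, no quadrant
  ambiguity); values are reported as computed, signed; the validated
  oblique sites have positive angles by construction of their frames.
* Problem sizes in the test suite (≥1000 random configurations per
  geometry oracle, 16–24 synthetic cases in the Monte-Carlo checks) keep
  the full suite in the seconds-to-a-minute range while leaving
  Monte-Carlo margins comfortable.
* The packaged validation table is a transcription of the published
  12-implant table; a handful of run-together cells in electronic
  renderings were resolved against the neighbouring repeats and the
  aggregate statistics, which the transcription reproduces to the
  printed precision.
* The C1 in-plane axis sense (and hence the sign of C1 sagittal ProjA)
  follows the A-cranial-to-B convention; users digitising their own
  landmarks must follow the same placement, as no published sign
  convention exists.
* Ellipsoid fitting needs ≥9 well-spread surface samples; rank-deficient
  or non-elliptic fits raise a degeneracy error rather than returning a
  spurious axis.
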