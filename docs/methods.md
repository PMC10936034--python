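# Methods

## Measurement model

A subject is a *virtual patient*: facial surface scans in three
expressions (closed-lip, rest, wide smile) and upper/lower dental arch
scans, all rigidly registered into the closed-lip scan's space, plus
sparse annotations — ten named anatomical landmarks, one inferior
upper-lip border polyline per expression, and one closed gingival-margin
contour per tooth of interest (FDI 13–23, 31, 41). All coordinates are
millimetres; the files carry no unit field, this is a documented
contract of the formats.

Measurement proceeds in three steps: (1) the canonical head-pose frame
is constructed from five landmarks, (2) all geometry is expressed in
that frame, (3) nine esthetic parameters are evaluated by closed-form
operations on contour vertices and landmark points. No parameter reads
the facial surface itself; meshes are carried for registration,
visualisation and provenance.

### Canonical frame

The XY plane is the Frankfort horizontal plane through
`infraorbital_left`, `ear_superior_left` and `ear_superior_right`; the
Z axis is its normal through the interpupillary midpoint. Three choices
are open in that prescription and are fixed here:

* **Axis orientation**: +Z superior, +Y posterior, +X the subject's
  anatomical left, right-handed. X̂ is the unit projection of
  (left ear − right ear) onto the plane, Ŷ = Ẑ × X̂. With these signs
  every parameter formula yields conventional positive values for
  normal anatomy (positive overjet, positive E-line distance for a lip
  behind the line).
* **Ẑ sign**: chosen so the pupils map to Z > 0 (pupils sit superior to
  the Frankfort plane). The interpupillary midpoint cannot break this
  tie because it lies on the Z axis itself.
* **Origin**: the orthogonal projection of the interpupillary midpoint
  onto the plane — the unique point on both the plane and the Z axis.

Postconditions (enforced by tests): the three plane landmarks map to
|Z| ≤ 1e-9 mm, the interpupillary midpoint to |X|, |Y| ≤ 1e-9 mm, and
frame construction is idempotent. Degenerate inputs (plane-point
triangle area ≤ 1e-6 mm², inter-ear direction perpendicular to the
plane) are rejected rather than repaired.

### Registration

Scans are assumed registered, or are aligned by corresponding-landmark
least-squares (Kabsch; delegated to
`scipy.spatial.transform.Rotation.align_vectors`, which guarantees a
proper rotation) with optional point-to-point ICP refinement
(nearest-neighbour correspondences on a k-d tree, Kabsch update per
iteration, RMSD non-increasing, stop at `max_iter` or improvement
< `tol`). ICP that runs into a degenerate correspondence set (e.g. all
matches collapsing to one vertex) stops at the current pose rather than
erroring. Reflections are rejected at `RigidTransform` construction, so
no operation in the package can produce one.

### Parameter formulas and their edge rules

See the README table for the formulas. Numerical conventions:

* **Extrema are vertex-attained.** Contours are dense manual (or
  synthetic) traces; vertex resolution bounds the error. Ties are broken
  by lowest vertex index, making results deterministic and invariant to
  re-indexing a closed contour's start vertex.
* **Lip evaluation** at a tooth's X position uses exact segment–plane
  linear interpolation of the lip polyline (coincidence tolerance
  1e-9 mm), not nearest-vertex snapping — robust to sampling density.
  If the lip polyline does not span that X, the parameter is an
  explicit coverage error, never an extrapolation.
* **Sign/clamp rules**: incisor exposure at rest may be negative (lip
  covering the incisal edge) and is never clamped; gingival exposure
  when smiling is clamped to exactly 0 when the lip covers the gingiva.
  Overbite is negative in open bite.
* **Midline deviation** defaults to the *mesial* reading: the mean of
  the mesial-most X of the two upper central incisors (Xmax of the
  tooth on the −X side, Xmin of the other, sides identified by contour
  centroid), which equals the dental-midline offset and is 0 for a
  symmetric arch. A *literal* mode averaging Xmin of both incisors is
  retained; under any single X-direction convention it is offset from
  the midline by half a central-incisor width (−4.25 mm for a symmetric
  8.5 mm incisor), which is why it is not the default.
* **Per-parameter tooth assignment** is configuration
  (`AnalysisConfig`): lengths on 11/21, widths on 13–23,
  overbite/overjet on 11 vs 41 (the lower incisor is overridable),
  exposures on 11/21.

Parameters whose inputs are missing are reported in the `missing`
section of the report with the reason; a partial case never fails the
whole run.

## The phantom generator

`dentoface.phantom` constructs synthetic subjects directly in the
canonical frame and then maps them through an arbitrary rigid pose, so
the measured value of every parameter is known analytically:

* landmarks at population-plausible positions (pupils ±32 mm at
  Z = +8 mm, ears at Y = 78 mm on the plane, nose/chin profile in the
  sagittal plane); the upper-lip midpoint's Y realises the requested
  E-line offset, and the columella point is placed by rotating the
  base→lip direction by the requested nasolabial angle in the sagittal
  plane;
* crowns as rounded-rectangle outlines whose straight sides attain the
  requested width/length exactly; the lower incisors' top edge and
  contour depth realise overbite and overjet;
* lip borders as constant-height polylines across the anterior region
  (with a gentle posterior curve), so the exposure parameters hold
  exactly at any X within the incisor span;
* a coarse ellipsoidal face shell and thin extruded crown meshes, for
  file-format realism only.

Defaults are population-typical values (8.5 mm central-incisor width,
10.5 mm length, 2.5 mm overbite, 3.0 mm overjet, 3.0 mm rest exposure,
1.5 mm gingival display, 1.2 mm E-line distance, 96° nasolabial angle);
`random_truth` samples around them with dispersions typical of healthy
dentitions (~0.5 mm crown dimensions, ~0.7 mm occlusal relations,
~1 mm soft-tissue distances, ~8° nasolabial).

The generator *does not* emulate real crown morphology, asymmetric or
curved smile lines, soft-tissue deformation between expressions, or
scanner noise and holes. Passing round-trip tests therefore demonstrates
the correctness of the frame construction and formulas — not robustness
to anatomical variation or scan artefacts.

One coupling is worth noting: the smile lip is placed against tooth
11's gingival zenith, so when the two central incisors are given
different crown lengths the gingival display of tooth 21 differs by the
length difference; the ground-truth accessor (`PhantomTruth.expected`)
accounts for this.

### Simulated raters

`simulate_raters` perturbs each landmark pick with isotropic Gaussian
noise (default σ = 0.1 mm) and every contour vertex independently
(σ = 0.05 mm) per subject × rater cell, reruns the entire pipeline and
records one value per parameter family (tooth 11 for per-tooth
parameters). These noise levels model careful point picking on
sub-millimetre scans. A perturbed case that fails (e.g. lip coverage
lost) is retried with fresh noise up to 5 times. All randomness flows
from explicit seeds.

## Statistics

Reproducibility is summarised as ICC(2,1) — two-way random effects,
absolute agreement, single measures — computed in-package from the
two-way ANOVA mean squares:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

Absolute agreement is the appropriate model when raters are a random
sample of researchers and absolute values matter clinically; the
consistency variant ICC(3,1) is available behind a flag. A matrix with
exactly identical rater columns returns 1.0 exactly (special-cased to
avoid round-off in the mean-square ratio); zero total variance is an
explicit error. The implementation is verified against an independent
design-matrix least-squares ANOVA oracle (1e-10) and cross-checked
against `pingouin`'s ICC(A,1)/ICC(C,1) in the test suite.

Method comparison summarises paired differences as mean ± SD and gates
the test on Shapiro–Wilk normality of the differences at α = 0.05:
paired t-test when normality is not rejected, Mann–Whitney U otherwise.
(The U test on the two samples, rather than a paired signed-rank test,
follows the comparison procedure this workflow re-enacts.) Identical
inputs are reported as degenerate with no test. Standard test internals
are delegated to scipy; only the ICC variance components are in-repo.

## File formats

* PLY (ascii and binary little-endian) and OBJ (optional trailing
  `r g b` per vertex line) for meshes. Reading is delegated to
  `trimesh`; PLY *writing* is implemented in-package with
  double-precision vertex properties, because common exporters truncate
  to float32, which at head-scale coordinates (~100 mm) leaves ~2e-6 mm
  round-trip error — above the 1e-6 mm contract this package holds
  itself to. Out-of-range face indices and empty vertex lists are
  rejected at read time.
* Landmarks: JSON `{"expression": ..., "points": {name: [x, y, z]}}`
  with a closed vocabulary of ten names; unknown names are an error
  naming them.
* Contours: JSON list of labeled point sequences; FDI-numbered labels
  become closed tooth contours, lip labels
  (`upper_lip_inferior_{closed,rest,smile}`) become open polylines.
  Point order is preserved exactly (it is semantic for interpolation).
* Transforms: JSON row-major 4×4 homogeneous matrix.
* Reports: JSON (values + missing + provenance + config hash/version)
  and long-format CSV.

## Problem sizes and determinism

The test and acceptance workloads are sized for a desk run: 30 phantoms
for recovery, 10 poses for invariance, 10 seeded studies of 15 subjects
× 3 raters for the ICC re-enactment (a few seconds in total). Identical
inputs, configuration and seed produce byte-identical outputs
throughout; reports embed the configuration hash and package version.

## Known limitations

* Extrema are not sub-vertex interpolated; accuracy is bounded by
  contour sampling density (exact on the phantom's straight-sided
  crowns, ~half the vertex spacing on smooth real contours).
* The phantom's planar crown contours make overjet exact by
  construction; on real inclined incisors the measured overjet depends
  on which vertex attains the Z extreme, as it does in any
  vertex-based reading.
* ICC confidence intervals are not computed (point estimates only).
* Non-rigid registration, scale estimation, mesh repair and texture
  are out of scope; inputs are metric scans.
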