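# Methods

This note records the models, numerical choices and limitations behind
`rootaxis`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## The measurement chain

A tooth's root direction cannot be observed on a dental cast, so the
procedure measures it indirectly through three rigid superimpositions:

1. **Partial-scan merge.** An extracted tooth is scanned in two
   overlapping stages (crown plus cervical root; whole root plus part of
   the crown). The second stage is registered onto the first by trimmed
   ICP and the union is welded into a whole-tooth model. Quality metric:
   RMSD of the retained correspondences, with a rejection gate
   (default 0.05 mm, scaled to `4 * noise_sd` when the emulated scanner
   noise exceeds it).
2. **Tooth-to-cast superimposition.** Only the crown and the cervical
   band are used as the reference area; the transform carries the whole
   tooth, root included, into cast coordinates. The cervical band is
   included with the crown because the crown/root junction is visible on
   the casts being emulated.
3. **Prediction-to-cast superimposition.** The predicted teeth of a jaw
   form one joined model; a single rigid transform is fitted on the
   union of predicted crowns against the cast crowns, and the predicted
   roots are carried along.

Root axes are then estimated in cast coordinates: 50 points are placed
evenly over each root surface and the axis is the total-least-squares
line (principal eigenvector of the point covariance) through their
centroid. The discrepancy is `arccos(|u . v|)`; axes are undirected, so
angles live in [0, 90] degrees.

## Registration

* **Inner solver.** Kabsch/SVD with the reflection excluded by
  sign-correcting the smallest singular value. Exact for noiseless
  rigidly related point sets; degenerate (collinear, < 3 points)
  configurations raise.
* **Correspondences.** Area-weighted random samples of the moving
  surface (default 2,000 for standalone use, 1,000 in the study
  pipeline) matched to the *exact* closest point on the fixed surface —
  point-to-triangle, computed by a KD-tree-pruned query that provably
  agrees with the brute-force all-triangle scan. Vertex-to-vertex
  matching exists as an option.
* **Trimming.** The worst `trim_fraction` of correspondences is
  discarded each iteration. The merge step uses 0.35 (about a third of
  the root-side scan has no counterpart in the crown-side scan at the
  default 75% stage coverage); crown-to-cast alignments use 0.1.
* **Acceleration.** Point-to-point ICP contracts linearly and can creep
  for hundreds of iterations along near-symmetric directions. When two
  successive incremental updates point the same way, the implementation
  extrapolates by the geometric-series sum of the update (capped at
  25x) and keeps the jump only if the trimmed RMSD decreases. This
  preserves the monotone-RMSD property while converging in tens of
  iterations.
* **Initialisation.** Identity by default. A principal-axes prealignment
  (best of the four proper sign combinations) is available; the study
  pipeline uses a label-aware variant that orients the occluso-apical
  axis from the crown/root label centroids — partial tooth scans are
  nearly flip-symmetric tapered tubes, and a purely geometric start can
  otherwise pick an upside-down basin — and chooses the residual azimuth
  among 12 candidates (plus identity) by a median-trimmed RMSD score.
* **Convergence.** Change in retained-set RMSD below `convergence_tol`
  (1e-6 mm standalone, 1e-5 mm in the pipeline, where the quality gate
  is 0.05 mm and tighter tolerances only cost iterations).

## Root-surface sampling

"50 points uniformly distributed over the root surface" leaves the
algorithm open. Three are implemented:

* **`spiral` (default).** The surface is cut into 50 equal-area strata
  along its principal axis; each stratum receives one point at a
  golden-angle azimuth, with consecutive strata taking antipodal
  azimuths so first-order azimuthal moments cancel in pairs. Points are
  realised as exact closest points on the mesh to probes placed just
  outside the local surface radius, so every sample lies on a triangle.
  The net is fully deterministic.
* **`farthest_point`.** Area-weighted random oversample (25 x n) thinned
  by greedy farthest-point subsampling — visually even, seeded.
* **`random`.** Pure area-weighted sampling.

The default is the spiral net rather than farthest-point thinning for a
measured reason: on the synthetic roots (13-17 mm long, 2.5-4 mm neck
radius) the covariance eigen-gap amplifies sampling imbalance, and a
50-point farthest-point net leaves ~1.4 deg mean axis error (a pure
random sample ~4.6 deg), while the antipodally balanced net stays at
~0.2 deg mean / 0.5 deg max across tooth types. With two independently
sampled axes per tooth, only the balanced net keeps the end-to-end
angle error reliably below one degree. The stochastic samplers remain
available for sensitivity analysis, and the axis fit itself is
sampler-agnostic.

Axis fitting clamps dot products to [-1, 1] before `arccos`, warns when
the top two eigenvalues tie within 1e-9 (isotropic cloud, ambiguous
axis), and raises on coincident points.

## Synthetic teeth and the study generator

The generator emulates the study material, not tooth anatomy in the
statistical-shape sense:

* **Geometry.** Surfaces of revolution with elliptical cross-sections:
  a tapered root ending in an apex vertex, a one-face-ring cervical band
  at the crown/root junction, and a crown cap that flattens
  labio-lingually toward the incisal edge (incisors) or narrows to a
  cusp (canines). Crown heights / root lengths / crown widths default to
  textbook averages per tooth type and jaw (e.g. mandibular central
  incisor 9.0 / 12.5 / 5.3 mm) with +/-5% per-tooth size jitter in
  study generation; the emulated study reports no specimen morphometry,
  so these defaults are documented as conventional rather than fitted.
* **Asymmetry, deliberately.** A fixed azimuthal profile (egg-shaped
  first harmonic plus a second-harmonic "developmental groove",
  amplitudes 5% and 4.5%) and a labial crown bulge break the rotational
  near-symmetry of a revolved surface; without them, crown-based ICP has
  a shallow twist direction and converges badly, which is a mesh-model
  artefact rather than a property of real crowns. Ring centroids are
  re-centred so the asymmetry cannot tilt the construction axis; 0.02 mm
  radial vertex jitter adds per-seed surface texture.
* **True axis.** The construction axis (+z) through the root-vertex
  centroid, recorded before any root-curvature bend. With zero
  curvature (the default) the dense root vertices recover it to ~1e-3
  degrees, so it is an exact oracle at the 0.1-degree scale of interest.
* **Scans.** Each stage keeps 75% of the tooth height (so the stages
  share 50% and trimmed ICP at 0.35 can reject the unmatched part —
  coverage below about 2/3 would exceed the 0.5 trimming invariant).
  Gaussian noise (default 0.01 mm SD) is applied along vertex normals,
  emulating surface-scanner acquisition error; each scan gets an
  arbitrary pose (<= 10 deg, <= 3 mm by default).
* **Predictions.** The root (only) is rotated about the cervical-band
  centroid by tip-about-y composed with torque-about-x. The injected
  discrepancy is the rotation angle of the composed matrix (from its
  trace). The study generator draws per-tooth discrepancies from a
  normal truncated to [0, 89] deg (defaults mean 9.7, SD 7 — matching
  the discrepancy scale the pipeline must resolve, 2-38 deg) and solves
  a one-dimensional root-finding problem (Brent) so the composed
  rotation angle equals the draw exactly at a random tip/torque azimuth.
* **Casts.** Crown + cervical submeshes placed along a circular arch
  with per-vertex tooth ids, so each cast crown is recoverable;
  overlapping placements warn rather than fail (overlapping predicted
  roots are a finding, not an error).
* **Composition.** At n = 55 the jaw/type allocation is 3/3/4 maxillary
  and 14/13/18 mandibular central/lateral/canine; other n use
  largest-remainder allocation of the same proportions.

What the generator does **not** emulate: real enamel texture, crown
wear, restorations, curved or multi-rooted anatomy in the default
configuration, cast deformation, scanner-specific artefacts
(holes, spikes), or segmentation errors. Passing the recovery tests
therefore shows that the measurement chain is unbiased and precise for
clean single-rooted geometry with bounded Gaussian surface noise — not
that any particular commercial predictor is accurate, and not that the
pipeline is robust to pathology-grade inputs.

## Statistics

* Descriptives use the n-1 SD and midpoint medians; display rounding
  (mean/median/range 1 dp, SD 2 dp) is separate from stored full
  precision.
* Limits of agreement: mean +/- 1.959964 x SD of paired differences.
* Kruskal-Wallis: midranks, tie-corrected H, chi-square p with k-1 df;
  a label-permutation p is available for very small groups.
* Sample size: the one-sample (paired-difference) normal-approximation
  formula with a floor of 2; with alpha 0.05, power 80%, SD 7 deg and
  delta 3 deg it gives 43, which is the reproduction target fixing the
  formula choice (the source study does not name one).

## Problem sizes and runtime

Default meshes are ~1,600 vertices / 3,200 faces per tooth (resolution
level 1); ICP uses 1,000 surface samples in the pipeline. A 55-tooth
study runs in about two minutes on one CPU; the acceptance script's two
studies plus the repeated-measurement analysis take a few minutes. These
sizes were chosen as the point where halving them starts to move
recovered angles by more than ~0.1 deg, i.e. accuracy saturates.

## Known limitations

* The spiral sampler assumes an elongated surface (it stratifies along
  the principal axis); it is not meaningful for blob-like regions.
* Point-to-point trimmed ICP needs the label-aware prealignment for
  partial scans; with unlabeled meshes and large pose offsets it can
  settle in a flipped basin.
* `detect_root_overlap` reports interpenetration and proximity of
  surfaces; it does not compute intersection volumes.
* The injected-angle oracle compares the rotation angle of the composed
  root rotation with the angle between fitted axes. These coincide
  exactly when the rotation axis is perpendicular to the root axis; at
  the tip/torque mixes the generator draws, the residual difference is
  below ~0.1 deg for discrepancies under 25 deg and bounded by ~0.5 deg
  at 38 deg, which is inside the stated recovery tolerances.
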