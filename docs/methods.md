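# Methods

This note documents the models, numerical choices and open design
decisions behind `gustoface`, in the spirit of a statistics package's
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A **landmark stream** is one tasting video: an ordered sequence of
frames, each carrying indexed 3D landmarks in the estimator's
normalised units, a validity flag (false where the estimator failed),
and inclusive frame bounds for the tasting section SI (strip in mouth)
and the optional post-tasting section SII. Coordinates are never
converted to pixels: every downstream measure is a ratio or an angle,
so the unit cancels.

Frames with `valid=False` are excluded from all measure computation and
are never interpolated — gaps simply shorten the series. The per-stream
valid fraction is reported exactly as valid/total.

The **53-landmark map** (brows 5+5, eye contours 18+18, nose tip, inner
eye corners, mouth corners, mid lips) ships as an editable JSON file of
face-mesh indices. The published study that motivates this layout does
not list its landmark indices, so the default map is an *approximation*
of the depicted regions using MediaPipe-canonical indices where they
are unambiguous; any 53-id map with the same region structure can be
substituted via config. Left/right names follow the observer of the
video, not the subject.

## The twelve measures

All constructions are planar in the x–y image plane by default
(`coordinate_mode: 2d`); a `3d` switch uses full Euclidean distances
for the distance-family measures. Rationale: the angle and area
measures are inherently planar constructs, and estimator depth is the
least reliable coordinate.

* **Reference distance** r: right inner eye corner to nose tip,
  per frame. Distances divide by r, the aperture by r², making every
  measure dimensionless and invariant under translation, in-plane
  rotation and uniform scaling of the landmarks. A frame with r below
  1e-12 is degenerate: dropped and counted, never imputed.
* **Eyebrow elevation**: distance from the *geometric median* of the
  five brow points to the nose tip, over r. The geometric median (not
  the coordinate-wise median) is used because it is equivariant under
  similarity transforms; the coordinate-wise median is not
  rotation-equivariant and would leak head roll into the measure. It is
  computed exactly at a data point when the vertex optimality condition
  holds (resultant of unit vectors ≤ multiplicity), otherwise by
  Weiszfeld iteration handed over to a damped Newton polish (Weiszfeld's
  linear rate collapses near, but not at, a data point; the objective is
  smooth there and Newton is quadratic). Batched agreement with an
  independent scalar implementation is at the 1e-13 level.
* **Eyebrow tilt**: the unsigned acute angle in [0°, 90°] between the
  total-least-squares line through the five brow points (principal axis
  of the centred 2×2 scatter, angle ½·atan2(2Σxy, Σx²−Σy²)) and the
  inner-eye-corner line. TLS rather than a regression of y on x keeps
  the fit rotation-equivariant. Whether the source analysis signed its
  tilt is unknowable from its description; unsigned is the default and
  the folding is config-visible.
* **Eyebrow shape**: interior angle at the middle (3rd) brow landmark
  between segments to the endpoints (1st, 5th), in [0°, 180°] via a
  clipped arccos.
* **Palpebral aperture**: absolute shoelace area of the ordered eye
  contour over r². Self-intersecting contours produce a warning, not an
  error, and the absolute value is returned. Scaling by r² (rather than
  leaving the area unscaled) keeps the measure dimensionless like the
  distances; the source only states that distance measures were scaled,
  so this is exposed in config by swapping the map/mode, and documented
  here as our choice.
* **Lip elevation (upper/lower)** and **mouth corner (L/R)**:
  nose-tip distances over r.

Measures are computed on every retained frame regardless of expression
state, because peak-expression frames cannot be identified reliably and
reactions evolve asynchronously across facial regions. A centred
moving average (default window 5, odd windows only) exists **for
display only**; SDs, ANOVA and classifier features always use
unsmoothed series.

## Per-video summaries and group statistics

The unit of analysis is the per-video sample SD (denominator n−1,
configurable) of each measure over the retained frames of the
configured sections — SI+SII concatenated by default, since reactions
continue after strip removal; SI-only and SII-only are config options.
Single-frame videos yield SD 0 with a warning.

* **Kruskal–Wallis H** (tie-corrected, χ² p-value on k−1 df) compares
  hedonic ratings across sex, age, strip order (within each taste) and
  across tastes. df is always k−1 for k non-empty groups.
* **One-way ANOVA** per measure compares the per-video SDs across taste
  categories and across hedonic scores — two separate one-way analyses,
  main effects only. Zero within-group variance with non-zero
  between-group variance is reported explicitly as F = ∞, p = 0.
* **Grouped distributions** give n, median, quartiles (linear
  interpolation) and Tukey 1.5·IQR whiskers per group and measure.
* No multiple-testing correction is applied; the report's manifest
  counts the tests run so readers can apply their own.

Whether the source analysis fed the ANOVA per-video SDs or frame-level
values is not stated; per-video SDs are the default here, consistent
with the feature matrix used for ranking.

## Importance ranking and classification

Features are the 12 per-video SD values; rows with undefined SDs are
dropped and counted. Two rankings are produced:

* **Trees**: impurity-based importances of an extremely-randomised
  trees classifier with 200 trees, √p features per split, min 5
  samples to split, min 2 per leaf, averaged over 20 refit seeds
  (single-seed importances are unstable at a few hundred rows); weights
  sum to 1 and runs are bit-reproducible given the base seed.
* **PCA**: features are standardised, components with correlation-
  matrix eigenvalue > 1 are retained (Kaiser criterion), and each
  feature is scored by its communality over the retained set,
  w_j = Σ_k λ_k·V²_kj. Two non-obvious facts motivate this rule: over
  *all* components the communality of standardised data is exactly 1
  for every feature (so aggregating across the full spectrum is
  uninformative by construction), and absolute- rather than
  squared-loading aggregation rewards features with diffuse loadings on
  many middling components over features concentrated on the dominant
  ones. The source analysis names PCA but not its ranking rule; this
  construction is ours.

`compare_rankings` reports top-k overlap and the Spearman correlation
of the two rank vectors. Classification accuracy uses subject-grouped
k-fold cross-validation so no child appears on both sides of a fold;
per-class accuracies and the confusion table are reported with the
chance level (1/number of classes). No claim is made of reproducing
any particular study's ranking order, which is data-dependent.

## Synthetic cohorts

The generator emulates the data-generating structure of a remote
taste-strip session, not its photometry. One video =

1. a mirror-symmetric neutral template (53 landmarks, nose tip at the
   origin, inter-ocular distance 0.42 normalised units);
2. expression events: localised displacements of landmark regions
   (brow raise = vertical offset, mouth-corner pull = lateral + downward
   offset, lip raise/depress, eye squint = contraction toward the
   contour centroid), with ramp/pulse/sustained envelopes, 30–90 frame
   durations, 2–3 events per active region, amplitudes in fractions of
   the inter-ocular distance. L/R pairs of a bilateral group share
   onset, duration, profile and realisation noise — brow raises and
   smiles engage both sides of a face — which also reproduces the
   left/right symmetry seen in real measure pairs;
3. isotropic Gaussian landmark noise, σ = 0.002 normalised units
   (~0.5% of inter-ocular distance): a per-frame *jitter*, deliberately
   below a mesh estimator's absolute accuracy, which is dominated by
   slowly-varying bias that the SD features do not see. The nose tip
   and inner eye corners receive 0.3× this σ: they sit on semi-rigid
   anatomy and are tracked far more stably than deformable regions —
   the very property that makes them usable as the scaling reference.
   Noise is applied in face coordinates *before* the rigid motion,
   because estimator error scales with the face in the image; applying
   fixed-amplitude noise after the scale drift would couple apparent
   noise level to camera distance and correlate all measure SDs
   through an artefactual common factor;
4. rigid-motion nuisance: translation and in-plane-rotation random
   walks and a smooth log-scale drift (camera hand-shake and approach).
   Because the measures are similarity-invariant, enabling motion
   changes per-video SDs only through its interaction with noise and
   drop-out — verified to be under 5% relative in the median;
5. estimator drop-out: each frame invalid with probability 0.026 (the
   observed real-world failure rate), emitted with no coordinates.

Cohorts draw ages from the published study's age-frequency table
(median 8.5 y, SD 1.46 at n = 64), sex from its 36:28 split, strip
order uniformly from the three randomised sequences (control strip
always first, as a practice trial), and hedonic scores from per-taste
distributions peaked at 3 (control), 5 (sweet), 1 (bitter) and
near-uniform (sour). A subject-level lognormal expressiveness factor
(σ = 0.2) scales all of a child's event amplitudes. Default per-taste
effect profiles loosely encode observed patterns (bitter → lower-lip
activity, sweet → brow raise, observer-right brow stronger) but are
configuration, not hard-coded truth; `eyebrow_only_effects()` builds the
single-signal cohorts used by the recovery checks. Video length
defaults to 300 SI + 185 SII frames at 30 fps, matching the real
studies' ≈485 processed frames per video.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: appearance-driven estimator failure modes
(landmark error correlated with pose and lighting), temporally
correlated estimator bias, out-of-plane head rotation (only in-plane
rotation and scale stand in for pose change), co-articulated whole-face
expressions beyond region events, and any typology of inter-individual
reaction styles (a subject random effect exists; no claimed clusters).

## Determinism and the pipeline

Everything randomised is driven by explicit seeds (numpy `Generator`);
cohorts are byte-reproducible, tree rankings are reproducible given the
seed list, and two `report` runs with the same config and seeds produce
byte-identical output files. The run manifest records the config
snapshot, input SHA-256 digests, counts of dropped frames/videos and
warnings; stage timings go to the log stream only, so output
directories stay comparable byte-for-byte.

Problem sizes used by the shipped checks: geometry oracles on 1,000
random frames; null calibration with 1,000 replicates at 3 groups of
15–20; recovery on 20 cohorts of 40 subjects (160 videos) each;
drop-out emulation over 100 seeds at 500 frames. These sizes give
binomial standard errors comfortably inside the stated tolerances
(e.g. ±0.007 on a 5% rate at n = 1000).

## Known limitations

* The default landmark map approximates the intended regions; analyses
  of real streams should verify the map against their estimator version.
* The hedonic score is modelled as categorical for classification and
  rank-based tests; no ordinal regression is provided.
* The aperture is an area, so partial eye closure and squint are
  conflated; pupil size is not available from mesh landmarks at all.
* ANOVA on SDs inherits the usual caveats of variance-of-variance
  statistics at short series lengths.
* The optional raw-video adapter (external face-mesh estimator → the
  documented stream schema) is out of the core surface and not bundled.
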