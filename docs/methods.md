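# Methods

## Data model and conventions

A recording is a frames × 16 × 3 array of keypoint positions in
millimetres (stored on disk as a frames × 48 HDF5 dataset,
`keypoints3d`, with `fps` and `keypoint_names` attributes). The keypoint
order — nose, ears, neck, limbs, claws, back, tail points — is a single
source of truth (`etho3d.vocab.KEYPOINT_NAMES`); any reordering fails
validation. The coordinate frame has its origin at the centre of the arena
floor with z the height above the floor; the arena is a cylinder of radius
250 mm partitioned into center (< 75 mm), middle (75–150 mm) and
peripheral (150–250 mm) rings by the radial position of the back keypoint.
Zone intervals are half-open `[lo, hi)` except the outermost, which is
closed at the radius; frames beyond the radius clamp to peripheral and are
counted.

All rule thresholds live in `RuleConfig` in the natural units (mm, mm/s,
frames) so they read in their conventional units. Every threshold comparison is
strict.

## Ethogram revision

Raw 40-category labels are merged onto the 13 behaviors by a configurable
surjective map (the shipped default assigns contiguous id blocks; real
deployments supply their own annotation-derived map as YAML). The revision
stages then run in a fixed order:

1. **merge** raw → 13 behaviors;
2. **jumping** — per-frame runs of back z > 100 mm lasting ≥ 2 frames;
3. **vertical postures** — Rising/Climbing segments are re-split on
   segment medians (front-paw radius > 0.8 R and back z > 40 mm →
   Climbing up), then Rising segments with neck z > 50 mm for ≥ 15
   consecutive frames become Rearing;
4. **grooming** — Rearing/Climbing/Rising/Turning segments > 300 frames;
5. **pausing** — frames inside Sniffing, Stepping, Grooming, Turning,
   Rising or Trotting where both nose and back speed < 15 mm/s.

The order is forced by the rules' source sets: grooming consumes the
post-split vertical labels, and pausing's source set contains Grooming, so
pausing must run last. "Front paws near the edge" is evaluated on the
segment-median radial distance of the mean of the two front-limb
keypoints; "Turning" expands to both turning directions; pausing applies
at per-frame granularity (which subsumes the whole-segment reading when
every frame qualifies). Re-running stages 2–5 on their own output is a
fixed point, verified on randomized inputs alongside exact agreement with
a brute-force per-frame oracle.

## Kinematics

- **Speed**: XY displacement of a keypoint between adjacent frames × fps;
  the first frame copies the second; a centred 5-frame median filter
  (≈167 ms at 30 fps) with edge replication is applied to the *speed*
  series, not the positions. Path length applies the same policy to the
  displacement series before summation.
- **Gait**: 3D distance between the left fore and hind limbs per frame
  within each locomotor segment, smoothed by a centred moving average
  (default window 5 frames); peaks/valleys via prominence-thresholded
  local extrema (default prominence 0.10 × series range); stride length =
  mean of (peak − next valley), unpaired trailing peaks dropped; stride
  frequency = detected cycles / segment duration. Segments shorter than
  the window or without a peak–valley pair are flagged undefined, not
  errors. Note the boxcar smoother attenuates a sinusoidal gait of
  frequency f by sin(5πf/fps)/(5 sin(πf/fps)); reported stride lengths are
  therefore amplitudes *of the smoothed series*, consistent across groups.
- **Posture angles**: interior 3D angle at the neck (nose–neck–back,
  upper body) and at the back (nose–back–root-tail, lower body), degrees
  in [0, 180]; zero-length bone vectors flag the frame NaN.
- **Stretch ratio**: per-frame sum of 3D distances from the back to seven
  peripheral keypoints (nose, neck, four limbs, root tail), divided by a
  reference total and expressed in percent. The reference is the control
  group's mean total during Sniffing, so the control mean during Sniffing
  is 100% by construction.

## Metrics, transitions, statistics

Behavior fractions exist in two explicit modes, because both are standard:
segment-count fractions (occurrences / total occurrences) and frame
fractions (time share). Frequencies are occurrences per minute. Time
windows are equal consecutive slices; segments straddling a boundary are
split at it, so windowed counts conserve session totals. Similarity
between two windows is the mean Pearson correlation over *all* ordered
animal pairs (including self-pairs) of per-animal 13-behavior count
vectors; including self-pairs is what makes diagonal entries meaningful
population-consistency indices rather than constants equal to 1.
Zero-variance vectors are excluded from the mean with a logged count.

Transition models count consecutive-segment pairs; the behavior-level
diagonal is structurally zero. Cluster-level models collapse consecutive
same-cluster segments by default (a self-loop-preserving variant is
available). Group difference maps average per-animal probability matrices
(each animal weighted equally; animals lacking a row are excluded from
that row's cells) rather than pooling counts. Hub nodes rank states by
network degree — distinct partners with transition probability above a
floor (default 0, i.e. any observed edge) in either direction — with ties
broken by occupancy then name. Entropy is the occupancy-weighted
transition entropy rate in bits; the variant name is recorded with outputs
since several entropy conventions circulate.

Group comparisons follow the gated battery: Shapiro–Wilk on each group and
a median-centred Levene test at α = 0.05 select between the two-sided
independent t-test and the two-sided Mann–Whitney U; p-values are
Bonferroni–Dunn adjusted by the explicit family size (13 for
behavior-wise scans, 6 for the headline-phenotype family, passed
explicitly). A constant-valued group skips Shapiro–Wilk (undefined) and
falls through to the U test with a note.

## Classifier

Two-class LDA (scikit-learn, SVD solver) with leave-one-out
cross-validation; macro-F1 from pooled held-out predictions, ROC-AUC from
pooled held-out decision scores, and a full-data 1-D projection for
plots. Design choices that matter:

- **Z-scoring** is performed on the full feature matrix before
  cross-validation, matching the standard protocol; this leaks a small
  amount of scale information across folds, so a fold-safe mode
  (`standardize="per_fold"`) is provided.
- **Class priors are fixed at 1/2.** The cohort design is balanced; with
  empirical priors every leave-one-out training fold is unbalanced
  *against* the held-out animal, and the log-prior intercept biases pooled
  null scores so the permutation-null mean AUC sits near 0.42 instead of
  0.5. With equal priors the decision scores equal the closed-form
  pooled-covariance discriminant (verified to 1e-8 in tests) and the
  permutation null recenters near 0.5 (residual ≈ −0.02 from the
  training-mean shift inherent to pooled LOOCV scoring).
- Five-fold stratified CV is available (`cv="kfold"`) but LOOCV is the
  primary protocol.

Feature presets: `counts13` (segment counts of all 13 behaviors) and
`fractions4` (frame fractions of Running, Trotting, Walking, Pausing —
the behaviors with the strongest group contrasts).

## Synthetic cohorts

The generator emulates 30-minute open-field sessions, 30 fps, 19 animals
per group. Behavior is semi-Markov: the next behavior is drawn from
per-behavior transition weights (zero diagonal), dwell times are geometric
(memoryless, chosen for analytic tractability of recovery tests) with
per-behavior means — e.g. control means of 25–45 frames for most
behaviors, 350 for grooming bouts, 60 for pausing. The skeleton is built
from a body-centre random walk: constant per-frame step at the behavior's
speed (control locomotor means 250/150/80/40 mm/s for
Running/Trotting/Walking/Stepping, drawn per segment), heading diffusion
with deterministic bias during turning, steering toward a preferred radius
(120 mm control), and reflection at the wall. Vertical behaviors set the
back/neck heights the revision rules require with margin (jump back 120 mm,
climb back 55 / neck 60 mm at the wall after a radial dash, rear neck
65 mm, rise neck 45 mm); the left limb pair oscillates at the stride rate
(control 5 mm at 3.5 Hz) during locomotion; grooming/pausing shrink the
body scale to emulate curling; independent Gaussian jitter (0.3 mm SD) is
added to every keypoint. Raw 40-category labels are emitted per segment by
deterministic round-robin over each behavior's mapped ids, so the whole
raw vocabulary and the merge map are exercised. Between-animal variation
is lognormal with 8% CV on dwell, preference, speed and stride parameters.

The affected profile programs effect *directions*, not calibrated effect
sizes: locomotor speeds × 0.72, transition preference shifted from
locomotion toward pausing (pausing weight 3.0 vs 0.8) with longer pausing
dwell, stride amplitude 8 mm at 2.5 Hz, preferred radius 225 mm, and a
12-minute changepoint after which the pausing preference triples while
locomotor preferences shrink by the same factor (within-session motor
fatigue, used by the similarity sign-recovery test). A null manifest uses
the control profile for both groups. Per-animal seeds derive from the
manifest seed via `numpy.random.SeedSequence.spawn` in a fixed order, so
cohorts regenerate byte-identically and any animal can be regenerated
alone.

What the generator does *not* emulate: biomechanically realistic limb
trajectories, pose-estimation outlier structure (its noise is i.i.d.
Gaussian, not heavy-tailed), identity drift, or calibrated effect sizes.
Passing recovery tests therefore demonstrates that the pipeline measures
what the generator programs — directionally faithful statistics under
realistic sampling noise — not that real recordings would show effects of
these magnitudes.

## Problem sizes and numerics

The shipped analysis runs 19 + 19 animals × 30-minute sessions
(54 000 frames each) in well under a minute on one CPU; the type-I-error
check simulates 1000 null 13-metric families at n = 19 per group. Gated
test selection happens on the same data being tested, which inflates the
family-wise error of the battery slightly above the nominal Bonferroni
level (measured ≈ 0.053 at α = 0.05); this mirrors the field-standard
procedure and is left as-is. Median filters use edge replication;
fractions validate to unit sums within 1e-9; probability rows to 1e-12;
undefined quantities (empty gait segments, zero-variance correlations,
unvisited transition rows) are flagged or excluded with counts rather
than raised.
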