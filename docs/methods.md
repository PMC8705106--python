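# Methods

This note documents the models and procedures `gaitid` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions that keep results reproducible.

## Coordinate and indexing conventions

3D joint sequences use the Human3.6M 17-joint subset
(0 hip-center, 1/2/3 right hip/knee/ankle, 6/7/8 left hip/knee/ankle,
12 spine, 13 thorax, 14 neck/nose, 15 head, 17/18/19 left arm,
25/26/27 right arm) in a right-handed z-up frame: the ground is the x–y
plane, z points up, and coordinates are unitless because 2D-to-3D lifting
networks emit scale-free positions. OpenPose 2D output (COCO 18-keypoint
indexing, pixel coordinates, image origin top-left) is converted by direct
index mapping plus four synthesized joints: the hip center is the midpoint
of the two hips, the spine the midpoint of hip center and thorax (= COCO
neck), the neck/nose is the COCO nose, and the head the midpoint of the two
ears, falling back to the eyes when an ear is undetected. The head rule is
our choice — deterministic and built only from COCO face points; nothing in
the source indexing pins it down. Synthesized joints carry the minimum
confidence of their sources. Undetected joints (confidence 0) in a loaded
stream are gap-filled by linear interpolation over time, copying the
nearest valid frame at the edges, because the cycle extractor needs dense
ankle tracks.

## Gait-cycle extraction

The working signal is the Euclidean distance between the two ankles. Its
maxima are the instants of maximal foot separation — initial contact and
terminal stance — and a full gait cycle (two steps) is the event pattern
maximum → minimum → maximum → minimum → maximum. A single max–min–max run
covers only one step; five alternating events are needed for the eight
phases the features reference, so a cycle here always spans two steps and
consecutive cycles share their boundary maximum.

Processing order and defaults:

1. **Interpolation** — cubic splines per joint per axis, factor 5 (four new
   samples per original gap), applied to the *joint positions* rather than
   to the distance series so that every phase timestamp indexes an actual
   pose. Original frames are preserved bit-exactly at the knots. At 20–25
   fps input this yields a 100–125 Hz effective timeline, fine enough that
   event quantization errors stay below one percent of a stride.
2. **Smoothing** — discrete linear convolution of the distance series with
   a length-M uniform filter, M = 12 samples (≈ 0.1 s at the effective
   rate), "same" alignment. Output values are clamped into the input's
   range, so smoothing can never manufacture out-of-range values; the first
   and last M samples (whose averages include zero padding) are flagged and
   never eligible as extrema.
3. **Extrema detection** — a sliding window of N = 7 samples; a center is a
   maximum when the slopes from it to each of the 3 points on the left are
   all positive and to each of the 3 on the right all negative (mirrored
   for minima). Strict inequalities: plateaus and exact ties are not
   extrema. Same-type extrema closer than N samples merge onto the better
   one (larger maximum, smaller minimum; ties keep the earlier index).
4. **Low-persistence pruning** — residual estimator jitter that survives
   smoothing shows up as a shallow min–max wiggle riding a true peak:
   adjacent opposite-type events whose value difference is a few percent of
   a real swing. Adjacent event pairs with a drop below 20% of the median
   adjacent drop are cancelled, shallowest first; same-type neighbours
   exposed by a cancellation merge as in step 3. On noise-free signals this
   is a no-op. The 20% fraction sits in the wide gap between genuine swings
   (≈ 100% of the median) and jitter wiggles (≈ 1–10%) and is not
   sensitive within that gap.
5. **Segmentation** — maximal alternating runs yield cycles with
   t_a, t_d, t_h at the three maxima and t_c, t_f at the two minima.
   The intermediate phases have no event signature in the distance signal,
   so t_b, t_e, t_g are placed at the temporal midpoints of their flanking
   events. This is a convention, adequate for the features that reference
   them, not a biomechanical event detection.

## The feature catalogue

Twenty-six values per cycle (fixed column order; see `features.FEATURE_NAMES`).

* **Angles** (degrees, vertex angles in [0, 180]): knee-flexion extremes are
  the max/min over the whole cycle of the knee vertex angle
  (∡(ankle, knee, hip)); a *smaller* vertex angle means *more* flexion.
  Phase-anchored angles are evaluated at the pose nearest the fractional
  phase timestamp (ties to the earlier frame; the pose is never
  re-interpolated). Leg inclinations measure a shank against the
  world-vertical ray through the ankle, built by lifting the ankle by
  H = 1.0 along +z — any positive H gives the same ray, so the constant is
  arbitrary and fixed. A perfectly vertical shank has inclination 0
  (parallel rays). Two printed right-leg inclination definitions in the
  source material reference the same point twice; they are implemented
  with the lifted right-ankle point, mirroring the left-leg definitions.
* **Relative lengths** (unitless): per-frame segment lengths averaged over
  the cycle; the four thigh/calf lengths are divided by the upper-body
  length (hip-center→spine + spine→thorax), since absolute scale is
  meaningless in lifted coordinates.
* **Strides**: left stride is the distance the left ankle travels between
  initial contact (t_a) and terminal stance (t_d); right stride between
  t_d and terminal swing (t_h). Note these formulas measure the *swinging*
  foot only when the cycle starts with the appropriate parity; when a cycle
  starts on the opposite foot the measured "stride" is the planted foot's
  near-zero travel. The synthetic generator phases its bouts so the first
  detected maximum has the parity that makes both formulas measure a full
  stride.
* **Periods** (frames on the interpolated timeline): total frames in
  [t_a, t_h]; the right-foot/left-foot periods count frames where that foot
  is ahead along the walking direction, estimated as the root joint's
  ground-plane displacement from t_a to t_h (viewpoint-independent; "ahead"
  has no camera-frame meaning in unitless 3D). Ties count as right, so the
  two periods always partition the cycle. `main_foot` is 1 when the right
  foot leads at least half the cycle. It reconstructs a dominant-foot
  indicator that appears in the feature set of the source material without
  a printed definition.

Every feature is invariant to translation and to rotation about the
vertical axis; angles and ratios are additionally scale-invariant. General
3D rotations change inclination angles by construction (they are measured
against world-vertical, which matches the assumption that the ground is the
x–y plane).

## Class separability

For a labelled feature table, Σ_inter is the scatter of class-mean vectors
about the grand mean **of class means** (not the pooled row mean — the two
differ for unbalanced classes), and Σ_intra sums per-class scatters of rows
about their class mean, each scaled by 1/n_classes. The separability is
Ψ = tr(Σ_inter) − tr(Σ_intra): positive when classes sit further apart than
they spread. Features mix degrees, ratios and frame counts, so they are
z-scored before the traces by default (`standardize=False` gives the
raw-scale statistic). Ψ grows monotonically as class means are pulled apart
at fixed within-class spread.

## Ensemble classifiers

Three tree ensembles with fixed, seeded configurations:

| method        | configuration                              | split  |
|---------------|--------------------------------------------|--------|
| random forest | 750 trees, 6 candidate features per split  | 70/30  |
| XGBoost       | gbtree, depth 3, 300 boosting rounds       | 75/25  |
| LightGBM      | multiclass objective, 200 iterations       | 75/25  |

Splits are stratified by subject. LightGBM additionally runs with
`min_child_samples = 5` (its default 20 cannot split classes that own only
a dozen cycles) and falls back to the binary objective for two-class
tables. Feature importance uses each library's native measure
(impurity-based for the forest, gain-based for the boosters); rankings are
therefore comparable within a method, not across methods.
`evaluate_repeated` averages accuracy and macro F1 over independent
resplits (seeds derived from the base seed) and reports their SDs.

## Siamese LSTM similarity

Each cycle becomes a sequence of 18-component steps: the x, y, z positions
of joints 8, 7, 6, 3, 2, 1 (left ankle/knee/hip, right ankle/knee/hip, in
that order), root-centered per frame so the arbitrary origin of lifted
coordinates drops out, then linearly time-resampled to L = 50 steps so
pairs can be batched (pass `length=None` to keep native lengths). The
encoder is a single-layer LSTM with an 18-dimensional hidden state and
memory cell, written directly in numpy with manual backpropagation through
time; the twin branches are literally the same object, so weight sharing is
structural and similarity is exactly symmetric. A pair's similarity is
exp(−‖h_a − h_b‖₁) on the final hidden states, in (0, 1] with 1 for
identical inputs. Training minimizes the mean squared error between the
similarity and the pair label (same = 1, different = 0) with Adam
(learning rate 0.02 by default), default batch size 1024, 10 epochs;
the forget-gate bias starts at 1. Pairs are sampled balanced (half same,
half different, never a cycle with itself) from a seeded generator. The
same/different decision threshold is fitted on a held-out validation split
of the pairs (20%) by maximizing accuracy; closed-set identification
assigns a probe to the enrolled subject with the highest mean similarity
over its gallery cycles, ties to the lowest subject id. Training is
deterministic given the seed (single-threaded numpy).

## The synthetic walker

The generator's purpose is to endow subjects with identity-bearing gait
signatures that the downstream methods consume — not biomechanical
fidelity. It is a planar-limb pendulum model: the pelvis advances along +x
at stride_len × cadence with a small vertical bob; each thigh swings
sinusoidally about its hip (legs in antiphase); the knee flexes by
knee_amp · cos⁴(ψ), modulated per subject by a phase-shifted factor, which
vanishes with flat fourth-order contact at the instants of maximal foot
separation — so at measured contacts the legs are straight and the stride
formulas close exactly. The hip swing amplitude defaults to
asin(stride_len / (4 · leg_len)), the unique value for which the distance a
swinging ankle covers between consecutive contacts equals stride_len; an
explicit `hip_amp` decouples the two. One "stride" is one full gait cycle;
the ankle-separation signal peaks twice per stride, and the generator
returns the closed-form peak times as ground truth. Bouts carry ~0.3 stride
of margin before the first event and ~0.7 after the last so every requested
cycle survives the smoothing edge exclusion; the event phase is deliberately
misaligned from the sample grid (an exactly grid-centred symmetric peak
yields two tied samples, which the strict slope predicate rejects — real
signals never tie exactly).

Cohort sampling draws per-subject parameters from normal distributions
truncated to their invariants. Defaults (unitless lengths; leg ≈ 0.87):

| parameter   | mean | between-subject SD |
|-------------|------|--------------------|
| thigh_len   | 0.45 | 0.030 |
| shank_len   | 0.42 | 0.030 |
| torso_len   | 0.50 | 0.040 |
| stride_len  | 1.10 | 0.100 |
| cadence     | 1.00 strides/s | 0.100 |
| knee_amp    | 55°  | 6.0 |
| asymmetry   | 1.00 | 0.030 (clipped to [0.8, 1.2]) |

`phase_offset` is uniform on (−π, π) and shifts only the knee-waveform
modulation, never the gait events. Noise is additive isotropic Gaussian on
every joint coordinate, applied after the kinematics to mimic
pose-estimator jitter. Default cohort shape: 20 subjects × 12 cycles at
25 fps (the scale of a small indoor gait dataset); 20 fps and larger
cohorts (hundreds of subjects × 8 cycles) are supported by the same
machinery.

**What the generator does not emulate — and what that means for results.**
Real pose-estimator error is structured: temporally correlated drift,
depth-direction bias, gross outliers on occlusion, and bone lengths that
fluctuate with viewpoint. The generator's i.i.d. Gaussian jitter is the
*most favourable* error model for cycle-averaged features (means over ~250
interpolated frames suppress it by √N) and comparatively unfavourable for
the sequence model, which consumes per-step positions (root-centering even
adds the root's noise to all six joints). Consequently, on these synthetic
cohorts the feature-ensemble arm degrades more slowly with i.i.d. noise
than the Siamese arm — the opposite of what structured real-world estimator
error produces. Passing tests on this generator therefore demonstrate
correctness and robustness of the *mechanics* (extraction, features,
training, decision rules), not the real-data ranking of the two arms.

## Numerical conventions

* Phase timestamps are fractional frame indices; pose lookup takes the
  nearest frame, ties to the earlier one. `period` counts whole frames in
  [t_a, t_h].
* Stride features inherit the event quantization of the interpolated grid:
  an exactly symmetric walker still shows a ~1% left/right stride
  difference because consecutive events fall at different fractional
  offsets. Sub-sample event localization would remove this but is not part
  of the extraction method.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); repeated evaluations derive per-repeat
  seeds as base + index. Every stage — generation, extraction, features,
  ensemble training, LSTM training — is bit-reproducible given its inputs
  and seed.
* Degenerate inputs fail loudly: fewer than 4 frames cannot be
  spline-interpolated, a series shorter than the filter or window cannot be
  smoothed or scanned, zero-length angle rays and zero upper-body length
  raise with the offending feature named, and a non-finite training loss
  aborts with a diagnostic rather than returning a silently broken model.

## Known limitations

* The planar walker has no hip ab/adduction, pelvic rotation, or
  double-support dynamics; phases b, e, g are midpoint conventions.
* Inclination features assume a level ground plane; sequences from a tilted
  camera must be normalized before feature extraction.
* The extraction method's stride formulas are parity-sensitive (see above);
  on real data, bouts whose first detected contact has the "wrong" foot
  forward will yield near-zero strides for both features of every cycle.
* Identity association across multiple people in one video is out of
  scope; each OpenPose person index is treated as a separate stream.
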