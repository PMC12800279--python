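# Methods

This note documents the models and procedures implemented in `gaitkin`,
the assumptions behind them, the parameters that matter, and what the
synthetic experiments do and do not demonstrate.

## Angle convention and kinematics

Joint angles are *included angles* between adjacent segment vectors,
computed directly on camera-frame coordinates: with `a` the vector from the
mid landmark to the proximal one and `b` from the distal landmark to the mid
one, θ = arccos(a·b/|a||b|). Hip uses Root–IAS–FLE, knee uses IAS–FLE–FAL,
both sides, giving four channels (LHip, RHip, LKnee, RKnee) in degrees.
Consequences of this convention:

- 0° is a fully extended joint; the image of the map is [0°, 180°], so
  hyperextension has no sign. Signed conventions would need a reference
  plane, which a monocular camera frame does not reliably provide.
- The angle is invariant under any common rotation, translation and positive
  scaling of the three landmarks (tested to 1e-9°), which is what makes
  camera-frame angles usable without world-frame conversion.
- Numerically the implementation evaluates atan2(|a×b|, a·b), which is the
  same angle as the arccos form but well-conditioned near 0° and 180°
  (arccos alone loses ~√ε ≈ 1e-6° at the extended-leg boundary, which
  would dominate the forward-kinematics round-trip error budget).
- Ankle angles are out of scope: distal (toe) keypoints from monocular
  estimators are too unreliable to support them.

Frames missing any of the seven landmarks are dropped, not imputed, before
normalization; a series with fewer than four valid frames is rejected.

Time normalization maps every trial onto the canonical 101-point grid
(cycle positions 0–100 %). `linear` (default) interpolates piecewise-
linearly at positions i/100. `block_average` averages the input frames
falling in each of 101 equal bins [(i−0.5)/100, (i+0.5)/100), with the
lower edge closed (ties round up, avoiding banker's-rounding asymmetry) and
empty bins filled by linear interpolation between neighbouring non-empty
bins; it exists because frame averaging is the natural description of
downsampling when input rates far exceed the grid. Both are selectable in
the pipeline config.

The 20→7 marker reduction averages named source-marker groups into the
canonical landmarks. Real MoCap montages vary, so the default grouping
(pelvis cluster → Root, ASIS/iliac pairs → IAS, femoral condyle pairs →
FLE, malleoli + heel → FAL, toes unused) is an explicit, overridable
assumption, not a standard.

## Pose benchmarking (PA-MPJPE)

Predicted frames are aligned to ground truth by the closed-form similarity
transform (Umeyama): centre both point sets, take the SVD of the
cross-covariance, correct the sign so the rotation is proper (det = +1),
and solve the scale analytically as the ratio of traces. Reflections are
deliberately excluded — a mirror alignment would silently erase left/right
anatomy. PA-MPJPE is the mean Euclidean per-landmark error after this
alignment, aggregated as mean ± sd with scored/total frame counts per
stratum. Alignment is per frame by default (each frame gets its own
transform); a per-trial mode fits one transform to the whole trial.
Collinear (rank < 2) landmark configurations are rejected rather than
returning an arbitrary rotation.

## Cycle quality control

Cycles are clustered by k-means (k-means++ seeding, Euclidean distance on
flattened 4×101 matrices, k = 5, ≤ 100 update iterations, 10 restarts,
fixed seed). Channels share degree units, so no per-channel standardization
is applied. Design choices that were genuinely open:

- **Typical-cluster selection** is a heuristic — maximize (summed centroid
  channel ROM) × (membership size) — standing in for what is, in practice,
  a manual review step; an explicit override is always available and should
  be preferred when centroids can be inspected.
- **Reversed-cluster detection**: a cluster is a direction-reversal artifact
  if its left/right-swapped centroid correlates with the reference centroid
  above 0.9 *and* above its unswapped correlation. With symmetric gait
  (right ≈ left shifted by half a cycle) a mirrored cycle equals a
  half-cycle phase shift, so the swapped-correlation test is the right
  discriminator while plain distance is not.
- **Majority orientation**: the ROM×size heuristic can land on a
  mirror-dominated cluster, which would invert every subsequent decision.
  If the flagged-reversed clusters hold more trials than the typical ones,
  the two roles are therefore swapped. This assumes fewer than half of the
  trials are reversed — reasonable for a recording artifact; cohorts
  violating it need the manual override.
- **Flip correction** swaps LHip↔RHip and LKnee↔RKnee and leaves the time
  axis untouched. A `time_reverse` mode (swap + time flip) is provided
  because a direction artifact can also be described as an apparently
  time-reversed cycle; with near-symmetric gait the two corrections differ
  only at second order.

Subset 1 contains the typical clusters; subset 2 adds the flip-corrected
reversed trials. Every keep/flip decision is recorded in the subset
provenance map.

## Validation statistics

DTW uses the classic recurrence D(i,j) = c(i,j) + min(D(i−1,j−1),
D(i−1,j), D(i,j−1)) with no window constraint and no path-length
normalization; pointwise cost is |x−y| (univariate) or the Euclidean norm
(multivariate), and the optimal path is recovered by backtracking. The
permutation test shuffles the comparator series uniformly at random
(jointly across channels) and reports p = (1/N)·Σ𝕀(D⁽ᵏ⁾ ≤ D_obs) with
N = 8000 by default; shuffling one side suffices because the null of "no
temporal correspondence" only needs exchangeability of one series' time
order. The literal estimator can return p = 0 at resolution 1/N; a
`plus_one` smoothing option ((1+Σ𝕀)/(1+N)) is available but off by
default to keep the printed formula. For the null ensemble the same
recurrence is evaluated batch-vectorized across permutations (identical
arithmetic, cross-checked against the single-pair implementation in
tests), which is what makes 500-replicate calibration runs cheap.
Per-joint univariate DTW is the default; Pearson r uses the exact
two-sided t-test with n−2 degrees of freedom and rejects zero-variance
input rather than reporting r = 0.

## Phenotyping

The "cluster-centre" classifier is nearest-centroid: per-class mean of the
cycle matrices, Euclidean distance, ties broken to the first label in
sorted order. ROM reduction is 100·(ROM_ref − ROM_case)/ROM_ref computed
on class centroids per joint (ROM = max − min of the centroid series), with
peak-flexion difference max(ref) − max(case) alongside; reduction relative
to the healthy ROM is the stated convention. Classification metrics come
from the confusion matrix with SCI as the positive class; ratios with zero
denominators are reported as absent (`None`), never as 0. Both the
centroid classifier and the MLP are evaluated on the same stratified
held-out split (25 % by default) so their metrics are comparable.

## Supervised classification and attribution

The MLP is a single hidden layer of 100 ReLU units trained with Adam
(learning rate 1e-3) for at most 300 iterations on the flattened 404-vector
cycles; regularization is an L2 weight penalty (α = 1e-4) — the backend
network has no dropout layer, so weight decay plays that role. Training,
the train/test split and weight initialization all derive from one seed.

Shapley attribution uses permutation sampling: per Monte-Carlo draw, a
background cycle z and a random feature ordering are sampled, features are
switched from z's value to the instance's value one at a time in that
order, and each feature accumulates its marginal output change (model
output = predicted SCI probability). Exact enumeration over 404 features
is infeasible (2⁴⁰⁴ coalitions); with uniform-random orderings the
estimates converge to Shapley values under background imputation of absent
features. Two properties are exact by construction, not approximation:
the per-sample marginal contributions telescope, so
baseline + Σ attributions = model output at the instance for *any* sample
count, and two instances explained with the same seed share their
baseline. Default budget is 512 samples per instance (≈ 512·405 model
evaluations, batched).

Significant windows are contiguous runs of time points whose
|attribution| exceeds mean + 2·SD of all 404 |attributions| (an explicit
stand-in for a visual bounding-box criterion), merged per channel, signed
by the window's mean attribution, and ranked by total attribution mass.

## Synthetic gait generator

The generator is the package's controlled stand-in for clinical cohorts.
One cycle is a parametric template: hip flexion a raised cosine
(mean 25°, amplitude 15°), knee flexion the sum of two periodic Gaussian
bumps (18° at 15 % of the cycle, width 0.08; 60° at 72 %, width 0.10),
right channels equal to left at (s + 0.5) mod 1. These values resemble
normative sagittal curves while keeping every angle strictly inside
(0°, 180°): a template that crossed 0° could not be represented by an
included angle and would make the forward-kinematics round trip
ill-posed, which is why the hip curve is centred at 25° rather than lower.

Pathology is a per-channel affine compression toward the channel minimum:
θ' = min + f·(θ − min), so ROM scales by exactly f while the extended
baseline stays put — emulating reduced peak flexion rather than a shifted
posture. An optional smooth periodic time warp (two sinusoidal harmonics,
jitter SD in cycle fraction, monotonicity enforced) models timing
irregularity; channel extrema are restored after warping so the exact ROM
contract holds regardless.

Forward kinematics is a planar sagittal model in right-handed millimetre
coordinates (+x walking direction, +y up, +z mediolateral): the Root
translates at walking speed, IAS sit at the pelvis sides, and thigh/shank
directions are constructed inside the plane spanned by the parent segment
and the walking axis so that the included angles Root–IAS–FLE and
IAS–FLE–FAL equal the hip and knee channels *by construction* — angle
recovery is a strict inverse, closing the round trip to 1e-6° noiselessly.
Reversed trials mirror the lateral axis and swap left/right landmark
labels, reproducing the wrong-walking-direction artifact. Default study
conditions: 40 trials per class, 60–250 frames at 50 Hz, SCI ROM scale
0.5, angle noise SD 2°, keypoint noise SD 3 mm, 30 % reversed trials,
walking speed 1 m/s; a single seed drives all randomness and regeneration
is bit-identical.

What the generator does **not** emulate: pose-estimator failure modes
(occlusion, identity switches, depth bias), out-of-plane motion and
transverse/frontal-plane compensation, stride-to-stride variability within
a trial (each trial is one cycle), soft-tissue artifact, or any specific
pathological waveform beyond ROM reduction and timing jitter — the shape
of SCI compensation is modelled generically. Passing the synthetic
acceptance checks therefore demonstrates the *pipeline's* correctness and
sensitivity under known ground truth, not clinical performance on real
video-derived keypoints.

## Numerical choices and degenerate inputs

- Angles: atan2 formulation (see above); coincident landmarks raise a
  degenerate-landmark error instead of returning 0.
- Procrustes: rank-deficient configurations and fewer than three landmarks
  are rejected; scale is strictly positive by construction.
- k-means: fixed random state; 10 k-means++ restarts; empty-cluster
  handling is delegated to the backend implementation.
- Permutation p-values are super-uniform at resolution 1/N under the null;
  seeded runs reproduce exactly.
- Classifier tie-breaks are lexicographic in the label, making predictions
  order-independent.
- File writes are atomic (temp file + rename); reports embed the config
  hash and master seed.

## Problem sizes used in the checks

The test-suite and acceptance-script experiments use deliberately modest
sizes chosen to exercise every claim at comfortable statistical margins:
40+40-trial cohorts for end-to-end parameter recovery, 500 replicates ×
200 permutations for null calibration of the permutation test (99 %
binomial band around α = 0.05), 100 random frames for similarity-invariance
of PA-MPJPE plus 20 noisy frames against a numeric-optimizer oracle,
exhaustive path enumeration for all DTW instances with n·m ≤ 20, and 10–20
seeded repetitions of the planted-window attribution experiment
(128-sample attributions in the repetition loop, 512 for the additivity
check). Larger sizes change none of the qualitative outcomes; the margins
above are already wide at these scales.

## Known limitations

- The included-angle convention cannot represent hyperextension or signed
  frontal/transverse components; camera-frame angles are viewpoint-
  dependent summaries, not anatomical joint angles.
- Cluster-count k is fixed (default 5), not selected automatically; the
  typical-cluster heuristic assumes a majority of well-recorded,
  majority-orientation trials.
- The ROM-reduction percentage depends on the healthy centroid being a
  fair reference; with very small or imbalanced subsets the centroid is
  noisy and the percentage inherits that noise.
- Shapley estimates beyond the exact additivity identity carry Monte-Carlo
  error O(1/√n_samples); window boundaries should be read as approximate.
- The permutation test's literal estimator can report p = 0, which should
  be stated as p < 1/N.
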