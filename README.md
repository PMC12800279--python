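# gaitkin

Camera-frame gait kinematics for markerless clinical gait analysis: from 3D
lower-body keypoints to hip/knee flexion-angle time series, clustering-based
gait-cycle quality control, statistical validation against a motion-capture
reference, and interpretable phenotyping of spinal-cord-injury (SCI) versus
healthy gait.

## Who this is for

Monocular 3D pose estimators can recover lower-body joint positions from a
single video, which makes gait assessment feasible outside the motion-capture
lab — but the raw keypoint streams are noisy, unsynchronized, occasionally
recorded with the subject walking the "wrong" way across the camera view, and
not directly interpretable by clinicians. `gaitkin` is the analysis layer
that sits after pose estimation: it turns keypoint trajectories of seven
lower-body landmarks (Root, and left/right IAS, FLE, FAL — pelvis, femoral
epicondyle, lateral malleolus) into quality-controlled, comparable joint-angle
cycles and clinically legible summaries (per-joint range-of-motion loss,
discriminative gait-phase windows). Because clinical keypoint datasets are
rarely shareable, the package includes a synthetic gait generator with known
ground truth, so the full pipeline is testable end to end.

## What it computes

**Flexion angles.** For each frame, the hip and knee flexion angles are
included angles computed directly in the camera frame:

    θ = arccos( a · b / (|a| |b|) )

with `a` the proximal→mid segment vector and `b` the mid→distal one
(hip: Root–IAS–FLE; knee: IAS–FLE–FAL), so θ = 0° is a fully extended joint.
Each trial is resampled to the standard 101-point gait-cycle grid (0–100 %).

**Cycle quality control.** Cycles are clustered with k-means (k-means++
seeding, k = 5 by default) on the flattened 4×101 angle matrices. The
representative cluster is identified; clusters whose left/right-swapped
centroid correlates strongly with it are direction-reversed recording
artifacts and their trials are corrected by swapping left and right channels.
This yields *subset 1* (typical clusters only) and *subset 2* (subset 1 plus
the flip-corrected reversed trials).

**Pose benchmarking.** Predicted keypoints are scored against ground-truth
markers by PA-MPJPE: the mean per-joint Euclidean error after the optimal
similarity (Procrustes) alignment — rotation, positive scale and translation,
reflections excluded — reported as mean ± sd (n frames) per stratum. A
default 20→7 marker-averaging reduction maps full MoCap montages onto the
seven landmarks.

**Validation statistics.** Pipeline signatures are compared to a reference
trajectory per joint with (i) unnormalized dynamic time warping,
`D(X,Y) = min_π Σ d(x_i, y_j)`, (ii) a permutation test that shuffles the
comparator series N times (default N = 8000) and reports
`p = (1/N) Σ 𝕀(D_k ≤ D_obs)`, and (iii) Pearson correlation with a two-sided
t-test.

**Phenotyping and attribution.** A nearest-centroid classifier and per-joint
ROM comparison (`100 · (ROM_ref − ROM_case) / ROM_ref`) quantify the group
difference; a one-hidden-layer MLP (100 ReLU units, Adam, 300 iterations)
plus a permutation-sampling Shapley estimator attribute the SCI probability
to (channel, time-point) features and merge them into significant gait-phase
windows.

## Worked example

```python
from gaitkin import PipelineConfig, run_synthetic_study

cfg = PipelineConfig().reseeded(1)          # 40+40 trials, SCI ROM scaled 0.5
result, report = run_synthetic_study(cfg)

for joint, row in report["rom_comparison"].items():
    print(f"{joint}: ROM {row['rom_reference']:.1f} -> {row['rom_case']:.1f} deg "
          f"({row['reduction_pct']:.1f}% reduction)")
det = report["reversed_detection"]
print(f"reversed trials: {det['n_detected']} detected / {det['n_true']} injected "
      f"(precision {det['precision']:.2f}, recall {det['recall']:.2f})")
print(f"MLP held-out accuracy: {report['mlp_metrics']['accuracy']:.2f}")
```

prints

```
LHip: ROM 30.6 -> 15.3 deg (50.0% reduction)
RHip: ROM 31.0 -> 15.9 deg (48.8% reduction)
LKnee: ROM 58.1 -> 27.8 deg (52.2% reduction)
RKnee: ROM 58.6 -> 28.2 deg (52.0% reduction)
reversed trials: 26 detected / 26 injected (precision 1.00, recall 1.00)
MLP held-out accuracy: 1.00
```

The cohort was generated with every SCI joint's range of motion scaled to
0.5 of the healthy template and 2° of angle noise: the pipeline recovers the
planted ~50 % per-joint reduction from raw keypoints, identifies every
direction-reversed trial, and separates the classes cleanly. The same
stages are available from the shell (`gaitkin simulate / angles / normalize /
qc / benchmark / validate / phenotype / explain / run-all`).

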