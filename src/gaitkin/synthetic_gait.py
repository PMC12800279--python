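"""Synthetic gait cohorts with known ground truth.

Generates healthy and SCI-like trials as 3D keypoint trajectories via a
planar sagittal forward-kinematic model, so every downstream stage
(kinematics, cycle QC, validation, phenotyping) is testable without
clinical data. SCI pathology is emulated as a per-joint reduction of range
of motion (flexion scaled about the channel minimum) plus optional timing
jitter; recording artifacts are emulated as direction-reversed (laterally
mirrored, left/right-relabelled) trials.

Coordinates are right-handed millimetres: +x walking direction, +y up,
+z mediolateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .kinematics import (
    CHANNELS,
    LANDMARKS,
    JointAngleSeries,
    KeypointTrajectory,
)

RomScale = Union[float, Sequence[float], Dict[str, float]]


@dataclass(frozen=True)
class GaitTemplateParams:
    """Parametric sagittal gait-cycle template (one cycle, phase s in [0,1]).

    Hip flexion is a raised cosine, knee flexion the sum of two periodic
    bell-shaped bumps (loading-response and swing flexion peaks). Right-side
    channels are the left channels evaluated at ``(s + right_offset) mod 1``.
    Defaults resemble normative sagittal curves under the included-angle
    convention (all values strictly inside (0, 180) deg); they are fixture
    defaults, not measured values.
    """

    hip_mean: float = 25.0
    hip_amp: float = 15.0
    hip_phase: float = 0.0
    knee_bump1_amp: float = 18.0
    knee_bump1_center: float = 0.15
    knee_bump1_width: float = 0.08
    knee_bump2_amp: float = 60.0
    knee_bump2_center: float = 0.72
    knee_bump2_width: float = 0.10
    right_offset: float = 0.5

    def __post_init__(self) -> None:
        if self.knee_bump1_width <= 0 or self.knee_bump2_width <= 0:
            raise ValueError("bump widths must be > 0")
        for c in (self.knee_bump1_center, self.knee_bump2_center,
                  self.right_offset):
            if not 0.0 <= c < 1.0:
                raise ValueError("centers and right_offset must lie in [0, 1)")
        if self.hip_amp < 0 or self.knee_bump1_amp < 0 or self.knee_bump2_amp < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class SkeletonGeometry:
    """Segment lengths of the planar leg model, metres."""

    pelvis_half_width: float = 0.12
    root_height_above_pelvis: float = 0.15
    thigh_length: float = 0.42
    shank_length: float = 0.43

    def __post_init__(self) -> None:
        for name in ("pelvis_half_width", "root_height_above_pelvis",
                     "thigh_length", "shank_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a two-class synthetic cohort."""

    n_per_class: int = 40
    rom_scale_sci: RomScale = 0.5
    frame_count_range: Tuple[int, int] = (60, 250)
    fps: float = 50.0
    angle_noise_sd: float = 2.0
    keypoint_noise_sd: float = 3.0
    reversed_fraction: float = 0.3
    timing_jitter_sd: float = 0.02
    walk_speed: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversed_fraction <= 1.0:
            raise ValueError("reversed_fraction must lie in [0, 1]")
        lo, hi = self.frame_count_range
        if lo < 4 or hi < lo:
            raise ValueError("frame_count_range must satisfy 4 <= min <= max")
        for f in np.atleast_1d(np.asarray(_rom_vector(self.rom_scale_sci))):
            if not 0.0 < f <= 1.0:
                raise ValueError("rom_scale factors must lie in (0, 1]")


@dataclass
class TrialTruth:
    """Hidden generator ground truth attached to each synthetic trial."""

    reversed: bool
    rom_scale: np.ndarray  # per-channel factors, order of CHANNELS
    clean_angles: JointAngleSeries  # pathology applied, before any noise


@dataclass
class SyntheticTrial:
    trajectory: KeypointTrajectory
    label: str
    subject_id: str
    trial_id: str
    truth: TrialTruth


def _rom_vector(rom_scale: RomScale) -> np.ndarray:
    if isinstance(rom_scale, dict):
        return np.array([float(rom_scale[c]) for c in CHANNELS])
    arr = np.atleast_1d(np.asarray(rom_scale, dtype=float))
    if arr.size == 1:
        return np.full(len(CHANNELS), float(arr[0]))
    if arr.size != len(CHANNELS):
        raise ValueError("rom_scale must be scalar or one factor per channel")
    return arr.astype(float)


def _periodic_bump(s: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    d = s - center
    d -= np.round(d)  # wrap to [-0.5, 0.5): nearest image on the cycle
    return amp * np.exp(-0.5 * (d / width) ** 2)


def angle_template(params: GaitTemplateParams, phases: Sequence[float],
                   fps: float = 50.0) -> JointAngleSeries:
    """Evaluate the template at cycle phases (in [0, 1], nondecreasing)."""
    s = np.asarray(phases, dtype=float)
    if s.size == 0:
        raise ValueError("phases must be non-empty")
    if s.min() < 0.0 or s.max() > 1.0:
        raise ValueError("phases must lie in [0, 1]")
    if np.any(np.diff(s) < 0):
        raise ValueError("phases must be nondecreasing")

    def left(sv: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        hip = params.hip_mean + params.hip_amp * np.cos(
            2.0 * np.pi * (sv - params.hip_phase))
        knee = (_periodic_bump(sv, params.knee_bump1_amp,
                               params.knee_bump1_center, params.knee_bump1_width)
                + _periodic_bump(sv, params.knee_bump2_amp,
                                 params.knee_bump2_center, params.knee_bump2_width))
        return hip, knee

    lhip, lknee = left(s)
    rhip, rknee = left(np.mod(s + params.right_offset, 1.0))
    return JointAngleSeries(np.vstack([lhip, rhip, lknee, rknee]), fps=fps)


def apply_pathology(series: JointAngleSeries, rom_scale: RomScale,
                    timing_jitter_sd: float = 0.0,
                    rng: Optional[np.random.Generator] = None) -> JointAngleSeries:
    """Scale each channel's range of motion about its minimum.

    ``theta' = min(theta) + f * (theta - min(theta))`` per channel, so the
    output ROM is exactly ``f`` times the input ROM and the minimum (the
    extended posture baseline) is unchanged — reduced peak flexion, not a
    shifted baseline. An optional smooth periodic time-warp with jitter SD
    ``timing_jitter_sd`` (cycle fraction) is applied before scaling; channel
    extrema are restored after warping so ROM exactness holds regardless.
    """
    f = _rom_vector(rom_scale)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("rom_scale factors must lie in (0, 1]")
    if timing_jitter_sd == 0.0 and np.all(f == 1.0):
        return series.with_values(series.values.copy())
    values = series.values.copy()
    if timing_jitter_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        n = values.shape[1]
        t = np.linspace(0.0, 1.0, n)
        a = rng.normal(0.0, timing_jitter_sd, size=2)
        # keep the warp monotone: |w'(t) - 1| <= 2*pi*|a1| + 4*pi*|a2| < 1
        budget = 2.0 * np.pi * abs(a[0]) + 4.0 * np.pi * abs(a[1])
        if budget >= 0.9:
            a *= 0.9 / budget
        w = t + a[0] * np.sin(2.0 * np.pi * t) + a[1] * np.sin(4.0 * np.pi * t)
        warped = np.vstack([np.interp(w, t, ch) for ch in values])
        # restore per-channel extrema lost to resampling
        for ci in range(warped.shape[0]):
            lo_o, hi_o = values[ci].min(), values[ci].max()
            lo_w, hi_w = warped[ci].min(), warped[ci].max()
            if hi_w > lo_w:
                warped[ci] = lo_o + (warped[ci] - lo_w) * (hi_o - lo_o) / (hi_w - lo_w)
        values = warped
    mins = values.min(axis=1, keepdims=True)
    values = mins + f[:, None] * (values - mins)
    return series.with_values(values)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def forward_kinematics(angles: JointAngleSeries, geom: SkeletonGeometry,
                       walk_speed: float = 1.0,
                       direction: int = +1) -> KeypointTrajectory:
    """Planar sagittal forward kinematics: angles -> keypoint trajectory.

    The Root translates along the walking axis at ``walk_speed``; IAS sit at
    the pelvis sides; the thigh direction is constructed so the included
    angle Root-IAS-FLE equals the hip channel exactly, and likewise
    IAS-FLE-FAL equals the knee channel, making the angle recovery a strict
    inverse in the noiseless case. ``direction=-1`` mirrors the lateral axis
    and swaps left/right landmark labels (the reversed-trial artifact).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if not np.all(np.isfinite(angles.values)):
        raise ValueError("angles must be finite")
    n = angles.n_frames
    mm = 1000.0
    xhat = np.array([float(direction), 0.0, 0.0])
    t = np.arange(n) / angles.fps
    root_y = mm * (geom.shank_length + geom.thigh_length
                   + geom.root_height_above_pelvis)
    root = np.column_stack([direction * walk_speed * mm * t,
                            np.full(n, root_y), np.zeros(n)])
    pelvis = root - np.array([0.0, mm * geom.root_height_above_pelvis, 0.0])
    half_w = direction * mm * geom.pelvis_half_width

    out: Dict[str, np.ndarray] = {"Root": root}
    for side, zsign in (("L", -1.0), ("R", +1.0)):
        ias = pelvis + np.array([0.0, 0.0, zsign * half_w])
        hip = np.radians(angles.channel(f"{side}Hip"))
        knee = np.radians(angles.channel(f"{side}Knee"))
        fle = np.empty((n, 3))
        fal = np.empty((n, 3))
        for i in range(n):
            u = _unit(root[i] - ias[i])
            w = _unit(xhat - np.dot(xhat, u) * u)
            bhat = np.cos(hip[i]) * u + np.sin(hip[i]) * w
            fle[i] = ias[i] - mm * geom.thigh_length * bhat
            u2 = bhat
            w2 = _unit(xhat - np.dot(xhat, u2) * u2)
            b2 = np.cos(knee[i]) * u2 + np.sin(knee[i]) * w2
            fal[i] = fle[i] - mm * geom.shank_length * b2
        out[f"IAS_{side}"] = ias
        out[f"FLE_{side}"] = fle
        out[f"FAL_{side}"] = fal

    if direction == -1:  # observer mislabels sides when walking the other way
        for a, b in (("IAS_L", "IAS_R"), ("FLE_L", "FLE_R"), ("FAL_L", "FAL_R")):
            out[a], out[b] = out[b], out[a]

    xyz = np.stack([out[name] for name in LANDMARKS], axis=1)
    return KeypointTrajectory(xyz, fps=angles.fps, trial_id=angles.trial_id,
                              subject_id=angles.subject_id, label=angles.label)


def generate_cohort(config: CohortConfig,
                    params: Optional[GaitTemplateParams] = None,
                    geom: Optional[SkeletonGeometry] = None) -> List[SyntheticTrial]:
    """Generate a labelled two-class cohort, fully reproducible from the seed.

    Healthy trials sample the template directly; SCI trials are
    pathology-scaled (``rom_scale_sci``) with timing jitter. White angle
    noise (deg) is added before forward kinematics and isotropic keypoint
    noise (mm) after; ~``reversed_fraction`` of trials are generated walking
    in -x and flagged in the hidden truth.
    """
    params = params or GaitTemplateParams()
    geom = geom or SkeletonGeometry()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.frame_count_range
    trials: List[SyntheticTrial] = []
    idx = 0
    for label in ("Healthy", "SCI"):
        rom = _rom_vector(config.rom_scale_sci) if label == "SCI" \
            else np.ones(len(CHANNELS))
        for i in range(config.n_per_class):
            n_frames = int(rng.integers(lo, hi + 1))
            series = angle_template(params, np.linspace(0, 1, n_frames),
                                    fps=config.fps)
            if label == "SCI":
                series = apply_pathology(series, rom, config.timing_jitter_sd, rng)
            clean = series
            noisy = np.clip(series.values
                            + rng.normal(0.0, config.angle_noise_sd,
                                         series.values.shape), 0.0, 180.0)
            reversed_ = bool(rng.random() < config.reversed_fraction)
            sid, tid = f"S{idx:03d}", f"T{idx:03d}"
            traj = forward_kinematics(
                JointAngleSeries(noisy, fps=config.fps, trial_id=tid,
                                 subject_id=sid, label=label),
                geom, walk_speed=config.walk_speed,
                direction=-1 if reversed_ else +1)
            traj.xyz = traj.xyz + rng.normal(0.0, config.keypoint_noise_sd,
                                             traj.xyz.shape)
            traj.valid = np.ones(traj.n_frames, dtype=bool)
            trials.append(SyntheticTrial(
                trajectory=traj, label=label, subject_id=sid, trial_id=tid,
                truth=TrialTruth(reversed=reversed_, rom_scale=rom.copy(),
                                 clean_angles=replace(clean, trial_id=tid,
                                                      subject_id=sid,
                                                      label=label))))
            idx += 1
    return trials


def generate_benchmark_pair(n_frames: int,
                            rotation: Optional[np.ndarray] = None,
                            translation: Optional[np.ndarray] = None,
                            scale: float = 1.0,
                            noise_sd: float = 0.0,
                            rng: Optional[np.random.Generator] = None,
                            ) -> Tuple[KeypointTrajectory, KeypointTrajectory]:
    """(ground truth, prediction) fixture for PA-MPJPE testing.

    prediction = scale * R @ truth + t + noise, frame-wise, with a single
    similarity transform for the whole trial.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = rng or np.random.default_rng()
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    series = angle_template(GaitTemplateParams(),
                            np.linspace(0, 1, max(n_frames, 2)))
    gt = forward_kinematics(series, SkeletonGeometry())
    gt.xyz = gt.xyz[:n_frames]
    gt.valid = gt.valid[:n_frames]
    pred_xyz = scale * np.einsum("ij,flj->fli", R, gt.xyz) + t
    if noise_sd > 0.0:
        pred_xyz = pred_xyz + rng.normal(0.0, noise_sd, pred_xyz.shape)
    pred = KeypointTrajectory(pred_xyz, fps=gt.fps, trial_id="pred")
    return gt, pred
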