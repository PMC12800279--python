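"""Procrustes-aligned keypoint scoring (PA-MPJPE).

Predicted keypoints are aligned to ground truth with the optimal
similarity transform (rotation, positive scale, translation; reflections
excluded) and scored as the mean per-joint Euclidean error. Alignment is
per frame by default; per-trial alignment is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinematics import KeypointTrajectory


@dataclass
class AlignmentResult:
    """Similarity transform mapping predicted points onto ground truth."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    scale: float
    translation: np.ndarray  # (3,)
    aligned_points: np.ndarray  # (n_landmarks, 3)

    @property
    def residual(self) -> float:
        """Not populated here; see pa_mpjpe_frame for the error metric."""
        raise AttributeError("use pa_mpjpe_frame for the aligned error")


def procrustes_align(pred: np.ndarray, gt: np.ndarray) -> AlignmentResult:
    """Closed-form similarity alignment of ``pred`` onto ``gt``.

    Both inputs are (n_landmarks, 3) with n >= 3 non-collinear points.
    The rotation comes from the SVD of the cross-covariance with the
    standard sign-flip correction (proper rotations only, so anatomical
    left/right cannot be mirrored away); scale is solved analytically.
    """
    P = np.asarray(pred, dtype=float)
    G = np.asarray(gt, dtype=float)
    if P.shape != G.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("pred and gt must both have shape (n_landmarks, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 landmarks for similarity alignment")
    mu_p = P.mean(axis=0)
    mu_g = G.mean(axis=0)
    Pc = P - mu_p
    Gc = G - mu_g
    # collinear (rank < 2) configurations leave the rotation underdetermined
    for name, M in (("pred", Pc), ("gt", Gc)):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= max(M.shape) * np.finfo(float).eps * max(s[0], 1.0):
            raise ValueError(f"rank-deficient (collinear) {name} configuration")
    H = Pc.T @ Gc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    scale = float(np.trace(D @ np.diag(S)) / np.sum(Pc ** 2))
    if scale <= 0:
        raise ValueError("non-positive optimal scale; degenerate configuration")
    translation = mu_g - scale * R @ mu_p
    aligned = scale * (R @ P.T).T + translation
    return AlignmentResult(rotation=R, scale=scale, translation=translation,
                           aligned_points=aligned)


def pa_mpjpe_frame(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-joint Euclidean error (mm) after Procrustes alignment."""
    res = procrustes_align(pred, gt)
    return float(np.mean(np.linalg.norm(res.aligned_points - np.asarray(gt, dtype=float),
                                        axis=1)))


@dataclass
class TrialScore:
    """Per-frame PA-MPJPE errors of one scored trial."""

    trial_id: str
    per_frame_error: np.ndarray
    n_frames_total: int
    stratum: str = ""

    @property
    def n_frames_scored(self) -> int:
        return int(np.asarray(self.per_frame_error).size)


@dataclass
class PAMPJPESummary:
    """Table-1-style summary cell: mean +/- sd over (n scored / total) frames."""

    per_frame_error: np.ndarray
    mean: float
    sd: float
    n_frames_scored: int
    n_frames_total: int

    def __str__(self) -> str:
        return (f"{self.mean:.1f} ± {self.sd:.1f} "
                f"({self.n_frames_scored}/{self.n_frames_total})")


def score_trajectory(pred: KeypointTrajectory, gt: KeypointTrajectory,
                     trial_id: str = "", stratum: str = "",
                     per_trial: bool = False) -> TrialScore:
    """Score all frames valid in both trajectories.

    Frames where either source lacks a landmark count toward
    ``n_frames_total`` only. ``per_trial=True`` fits one similarity
    transform to the stacked landmark cloud of the whole trial instead of
    aligning each frame independently.
    """
    n_total = min(pred.n_frames, gt.n_frames)
    both = pred.valid[:n_total] & gt.valid[:n_total]
    idx = np.nonzero(both)[0]
    if per_trial:
        P = pred.xyz[idx].reshape(-1, 3)
        G = gt.xyz[idx].reshape(-1, 3)
        aligned = procrustes_align(P, G).aligned_points
        d = np.linalg.norm(aligned - G, axis=1).reshape(idx.size, -1)
        errors = d.mean(axis=1)
    else:
        errors = np.array([pa_mpjpe_frame(pred.xyz[i], gt.xyz[i]) for i in idx])
    return TrialScore(trial_id=trial_id or pred.trial_id,
                      per_frame_error=errors,
                      n_frames_total=int(max(pred.n_frames, gt.n_frames)),
                      stratum=stratum)


def _summarize(errors: np.ndarray, n_total: int) -> PAMPJPESummary:
    errors = np.asarray(errors, dtype=float)
    return PAMPJPESummary(per_frame_error=errors,
                          mean=float(errors.mean()),
                          sd=float(errors.std(ddof=0)) if errors.size > 1 else 0.0,
                          n_frames_scored=int(errors.size),
                          n_frames_total=int(n_total))


def aggregate(trials: Sequence[TrialScore]) -> Dict[str, PAMPJPESummary]:
    """Mean +/- sd of per-frame errors per stratum plus ``overall``.

    Empty strata simply do not appear (absent, not zero). Aggregation is
    over frames, so the overall mean is the frame-weighted mean of the
    stratum means.
    """
    if not trials or all(t.n_frames_scored == 0 for t in trials):
        raise ValueError("no scored frames to aggregate")
    out: Dict[str, PAMPJPESummary] = {}
    strata = sorted({t.stratum for t in trials})
    for stratum in strata:
        errs = [t.per_frame_error for t in trials
                if t.stratum == stratum and t.n_frames_scored > 0]
        if not errs:
            continue
        n_total = sum(t.n_frames_total for t in trials if t.stratum == stratum)
        out[stratum or "unstratified"] = _summarize(np.concatenate(errs), n_total)
    all_errs = np.concatenate([t.per_frame_error for t in trials
                               if t.n_frames_scored > 0])
    out["overall"] = _summarize(all_errs, sum(t.n_frames_total for t in trials))
    return out
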