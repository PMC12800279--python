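"""Camera-frame joint kinematics.

Converts 3D keypoint trajectories of seven lower-body landmarks (Root,
left/right IAS, FLE, FAL) into hip/knee flexion-angle time series and
temporally normalized gait cycles on the canonical 101-point grid
(cycle positions 0-100%).

Angle convention: the included angle between the proximal-pointing segment
vectors, so 0 deg is a fully extended (straight) joint and values live in
[0, 180] deg. Angles are computed directly in the camera frame; no
world-frame transformation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical landmark names, left/right sides suffixed _L/_R.
LANDMARKS: Tuple[str, ...] = (
    "Root", "IAS_L", "IAS_R", "FLE_L", "FLE_R", "FAL_L", "FAL_R",
)

#: Angle channel order used throughout the package.
CHANNELS: Tuple[str, ...] = ("LHip", "RHip", "LKnee", "RKnee")

#: (proximal, mid, distal) landmark triple defining each angle channel.
CHANNEL_TRIPLES: Dict[str, Tuple[str, str, str]] = {
    "LHip": ("Root", "IAS_L", "FLE_L"),
    "RHip": ("Root", "IAS_R", "FLE_R"),
    "LKnee": ("IAS_L", "FLE_L", "FAL_L"),
    "RKnee": ("IAS_R", "FLE_R", "FAL_R"),
}

N_CYCLE_POINTS = 101


class DegenerateLandmarkError(ValueError):
    """Two landmarks of an angle triple coincide (zero-length segment)."""


@dataclass
class KeypointFrame:
    """A single frame of named 3D landmark positions in millimetres."""

    positions: Dict[str, np.ndarray]
    frame_index: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.positions = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.positions.items()
        }
        if self.valid:
            missing = [l for l in LANDMARKS if l not in self.positions]
            if missing:
                raise ValueError(f"valid frame missing landmarks: {missing}")
            for name, p in self.positions.items():
                if not np.all(np.isfinite(p)):
                    raise ValueError(f"non-finite coordinates for landmark {name!r}")


@dataclass
class KeypointTrajectory:
    """Per-frame 3D positions of the canonical landmarks over a trial.

    Attributes
    ----------
    xyz : ndarray, shape (n_frames, n_landmarks, 3)
        Positions in millimetres; NaN where a landmark is missing.
    landmarks : tuple of str
        Landmark name per column of ``xyz``.
    valid : ndarray of bool, shape (n_frames,)
        Frames with every canonical landmark present and finite.
    """

    xyz: np.ndarray
    landmarks: Tuple[str, ...] = LANDMARKS
    valid: np.ndarray = None  # type: ignore[assignment]
    fps: float = 50.0
    trial_id: str = ""
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_landmarks, 3)")
        self.landmarks = tuple(self.landmarks)
        if self.xyz.shape[1] != len(self.landmarks):
            raise ValueError("landmark axis does not match landmark names")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.xyz), axis=(1, 2))
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def index_of(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(f"unknown landmark {landmark!r}") from None

    def frame(self, i: int) -> KeypointFrame:
        pos = {name: self.xyz[i, j] for j, name in enumerate(self.landmarks)}
        return KeypointFrame(pos, frame_index=i, valid=bool(self.valid[i]))


@dataclass
class JointAngleSeries:
    """Four-channel (LHip, RHip, LKnee, RKnee) flexion-angle series, degrees."""

    values: np.ndarray  # (4, n_frames)
    fps: float = 50.0
    trial_id: str = ""
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(CHANNELS):
            raise ValueError("values must have shape (4, n_frames)")
        if self.values.shape[1] < 1:
            raise ValueError("angle series must contain at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle series contains non-finite values")
        if self.values.min() < -1e-9 or self.values.max() > 180.0 + 1e-9:
            raise ValueError("included angles must lie in [0, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.values[CHANNELS.index(name)]

    def with_values(self, values: np.ndarray) -> "JointAngleSeries":
        return replace(self, values=values)


@dataclass
class NormalizedCycle:
    """A gait cycle resampled onto the 101-point (0-100%) grid."""

    matrix: np.ndarray  # (4, 101)
    fps: float = 50.0
    trial_id: str = ""
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(CHANNELS), N_CYCLE_POINTS):
            raise ValueError(f"matrix must have shape (4, {N_CYCLE_POINTS})")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("normalized cycle contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.matrix[CHANNELS.index(name)]

    def flat(self) -> np.ndarray:
        return self.matrix.ravel()


@dataclass(frozen=True)
class MarkerReductionMap:
    """Grouping of source MoCap markers into the 7 canonical landmarks.

    Each canonical landmark is the arithmetic mean of its (non-empty) source
    marker group. The default 20-marker montage is a documented assumption
    (see :func:`default_reduction_map`) and fully user-overridable.
    """

    groups: Mapping[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        groups = {k: tuple(v) for k, v in dict(self.groups).items()}
        object.__setattr__(self, "groups", groups)
        if set(groups) != set(LANDMARKS):
            raise ValueError(f"reduction map must target exactly {LANDMARKS}")
        for target, sources in groups.items():
            if len(sources) == 0:
                raise ValueError(f"empty source group for target {target!r}")

    @property
    def source_markers(self) -> Tuple[str, ...]:
        seen: list = []
        for sources in self.groups.values():
            for s in sources:
                if s not in seen:
                    seen.append(s)
        return tuple(seen)


#: Default 20-marker lower-body montage. Pelvis cluster -> Root, ASIS/iliac
#: pairs -> IAS, femoral condyle pairs -> FLE, malleolus+heel -> FAL; the toe
#: markers are carried in the montage but enter no group.
DEFAULT_20_MARKERS: Tuple[str, ...] = (
    "SACR", "LPSI", "RPSI", "PELC",
    "LASI", "LILC", "RASI", "RILC",
    "LLFC", "LMFC", "RLFC", "RMFC",
    "LLMA", "LMMA", "LHEE", "RLMA", "RMMA", "RHEE",
    "LTOE", "RTOE",
)


def default_reduction_map() -> MarkerReductionMap:
    """The package's default 20-to-7 marker reduction."""
    return MarkerReductionMap(
        groups={
            "Root": ("SACR", "LPSI", "RPSI", "PELC"),
            "IAS_L": ("LASI", "LILC"),
            "IAS_R": ("RASI", "RILC"),
            "FLE_L": ("LLFC", "LMFC"),
            "FLE_R": ("RLFC", "RMFC"),
            "FAL_L": ("LLMA", "LMMA", "LHEE"),
            "FAL_R": ("RLMA", "RMMA", "RHEE"),
        }
    )


def reduce_markers(frame: KeypointFrame, reduction: MarkerReductionMap) -> KeypointFrame:
    """Average source-marker groups into the 7 canonical landmarks.

    Parameters
    ----------
    frame : KeypointFrame
        Frame containing (at least) every source marker of ``reduction``.
    reduction : MarkerReductionMap

    Returns
    -------
    KeypointFrame
        Frame with exactly the 7 canonical landmarks, each the arithmetic
        mean of its group's positions.
    """
    out: Dict[str, np.ndarray] = {}
    for target, sources in reduction.groups.items():
        pts = []
        for s in sources:
            if s not in frame.positions:
                raise KeyError(f"source marker {s!r} missing from frame "
                               f"{frame.frame_index} (needed for {target!r})")
            pts.append(frame.positions[s])
        out[target] = np.mean(np.stack(pts), axis=0)
    return KeypointFrame(out, frame_index=frame.frame_index, valid=frame.valid)


def three_point_angle(p_prox: np.ndarray, p_mid: np.ndarray, p_dist: np.ndarray) -> float:
    """Included flexion angle (degrees) at ``p_mid``.

    With ``a`` the vector from mid to proximal and ``b`` from distal to mid,
    the angle is ``arccos(a.b / (|a||b|))``: 0 deg for three collinear points
    in proximal-mid-distal order (a straight, fully extended segment chain),
    up to 180 deg.
    """
    a = np.asarray(p_prox, dtype=float) - np.asarray(p_mid, dtype=float)
    b = np.asarray(p_mid, dtype=float) - np.asarray(p_dist, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateLandmarkError("coincident landmarks give a zero-length segment")
    # atan2 of cross/dot: same included angle as arccos(a.b/|a||b|) but
    # well-conditioned near 0 and 180 deg (arccos loses ~sqrt(eps) there)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)),
                                       np.dot(a, b))))


def _angles_vectorized(prox: np.ndarray, mid: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """three_point_angle over frame stacks (n, 3); degrees."""
    a = prox - mid
    b = mid - dist
    if np.any(np.linalg.norm(a, axis=1) == 0.0) \
            or np.any(np.linalg.norm(b, axis=1) == 0.0):
        raise DegenerateLandmarkError("coincident landmarks give a zero-length segment")
    cross = np.linalg.norm(np.cross(a, b), axis=1)
    dot = np.einsum("ij,ij->i", a, b)
    return np.degrees(np.arctan2(cross, dot))


def compute_angle_series(traj: KeypointTrajectory) -> JointAngleSeries:
    """Hip and knee flexion angles, one value per valid frame.

    Hip: included angle Root-IAS-FLE; knee: IAS-FLE-FAL, both sides,
    evaluated directly on camera-frame coordinates. Invalid frames are
    dropped (their indices logged), not imputed.

    Raises
    ------
    ValueError
        If fewer than 4 valid frames remain (series unusable).
    """
    valid_idx = np.nonzero(traj.valid)[0]
    dropped = np.nonzero(~traj.valid)[0]
    if dropped.size:
        logger.info("trial %s: dropping %d invalid frames: %s",
                    traj.trial_id, dropped.size, dropped.tolist())
    if valid_idx.size < 4:
        raise ValueError(
            f"trial {traj.trial_id!r}: only {valid_idx.size} valid frames (< 4)")
    cols = {name: traj.index_of(name) for name in LANDMARKS}
    xyz = traj.xyz[valid_idx]
    values = np.empty((len(CHANNELS), valid_idx.size))
    for ci, ch in enumerate(CHANNELS):
        p, m, d = CHANNEL_TRIPLES[ch]
        values[ci] = _angles_vectorized(xyz[:, cols[p]], xyz[:, cols[m]], xyz[:, cols[d]])
    return JointAngleSeries(values, fps=traj.fps, trial_id=traj.trial_id,
                            subject_id=traj.subject_id, label=traj.label)


def normalize_time(series: JointAngleSeries, method: str = "linear") -> NormalizedCycle:
    """Resample an angle series onto the 101-point cycle grid.

    ``linear`` interpolates each channel piecewise-linearly at cycle
    positions i/100 (i = 0..100). ``block_average`` averages the input
    frames falling into each of 101 equal time bins (bin i centred at
    i/100); empty bins are filled by linear interpolation between
    neighbouring non-empty bins.
    """
    n = series.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames to normalize a cycle")
    t = np.linspace(0.0, 1.0, n)
    grid = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    if method == "linear":
        matrix = np.vstack([np.interp(grid, t, ch) for ch in series.values])
    elif method == "block_average":
        # bin i covers [(i-0.5)/100, (i+0.5)/100); floor(x+0.5) keeps the
        # lower edge closed so ties always round up, never banker-round
        bins = np.clip(np.floor(t * (N_CYCLE_POINTS - 1) + 0.5).astype(int), 0,
                       N_CYCLE_POINTS - 1)
        counts = np.bincount(bins, minlength=N_CYCLE_POINTS)
        nonempty = counts > 0
        matrix = np.empty((len(CHANNELS), N_CYCLE_POINTS))
        for ci, ch in enumerate(series.values):
            sums = np.bincount(bins, weights=ch, minlength=N_CYCLE_POINTS)
            means = np.divide(sums, counts, out=np.zeros_like(sums), where=nonempty)
            matrix[ci] = np.interp(grid, grid[nonempty], means[nonempty])
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedCycle(matrix, fps=series.fps, trial_id=series.trial_id,
                           subject_id=series.subject_id, label=series.label)
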