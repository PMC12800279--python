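"""File formats, configuration and pipeline orchestration.

Keypoints are interchanged as long-form CSV (``frame, landmark, x_mm,
y_mm, z_mm``); angle series and normalized cycles as wide CSV; manifests
and reports as JSON. The pipeline configuration is a single
schema-validated document (unknown keys rejected). ``run_pipeline``
chains kinematics -> normalization -> cycle QC -> validation ->
phenotyping -> classification/attribution and is bit-reproducible under
fixed seeds; all file writes are atomic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import cycle_qc, phenotyping, validation_stats
from .classify_explain import (
    AttributionMap,
    MlpConfig,
    extract_windows,
    shap_attribution,
    train_classifier,
)
from .kinematics import (
    CHANNELS,
    LANDMARKS,
    N_CYCLE_POINTS,
    JointAngleSeries,
    KeypointTrajectory,
    NormalizedCycle,
    compute_angle_series,
    normalize_time,
)
from .synthetic_gait import (
    CohortConfig,
    GaitTemplateParams,
    SkeletonGeometry,
    angle_template,
    generate_cohort,
)

logger = logging.getLogger(__name__)

KEYPOINT_COLUMNS = ["frame", "landmark", "x_mm", "y_mm", "z_mm"]


# ---------------------------------------------------------------------------
# atomic file helpers

def _atomic_write_text(path: Union[str, Path], text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, (set, frozenset)) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: Union[str, Path], obj) -> None:
    _atomic_write_text(path, json.dumps(_jsonable(obj), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# keypoint CSV

def write_keypoints(traj: KeypointTrajectory, path: Union[str, Path]) -> None:
    """Long-form keypoint CSV; rows with any NaN coordinate are omitted."""
    rows = []
    for i in range(traj.n_frames):
        for j, name in enumerate(traj.landmarks):
            p = traj.xyz[i, j]
            if np.all(np.isfinite(p)):
                rows.append((i, name, p[0], p[1], p[2]))
    df = pd.DataFrame(rows, columns=KEYPOINT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_keypoints(path: Union[str, Path], fps: float = 50.0,
                   trial_id: str = "", subject_id: str = "",
                   label: str = "unknown") -> KeypointTrajectory:
    """Parse a keypoint CSV; frames missing any canonical landmark are
    marked invalid; unknown landmarks are skipped with a warning; row
    order is irrelevant."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty keypoint file")
    missing_cols = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    coords = df[["x_mm", "y_mm", "z_mm"]].apply(pd.to_numeric, errors="coerce")
    frames_num = pd.to_numeric(df["frame"], errors="coerce")
    bad = coords.isna().any(axis=1) | frames_num.isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: malformed row at line {line}")
    unknown = sorted(set(df["landmark"]) - set(LANDMARKS))
    if unknown:
        warnings.warn(f"{path}: skipping unknown landmarks {unknown}")
        keep = df["landmark"].isin(LANDMARKS).to_numpy()
        df = df[keep]
        coords = coords[keep]
        frames_num = frames_num[keep]
    frame_ids = sorted(frames_num.astype(int).unique())
    row_of = {f: i for i, f in enumerate(frame_ids)}
    xyz = np.full((len(frame_ids), len(LANDMARKS), 3), np.nan)
    col_of = {name: j for j, name in enumerate(LANDMARKS)}
    fi = frames_num.astype(int).map(row_of).to_numpy()
    li = df["landmark"].map(col_of).to_numpy()
    xyz[fi, li] = coords.to_numpy()
    return KeypointTrajectory(xyz, fps=fps, trial_id=trial_id or path.stem,
                              subject_id=subject_id, label=label)


# ---------------------------------------------------------------------------
# angle-series / cycle CSV

def write_angle_series(series: JointAngleSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"frame": np.arange(series.n_frames)})
    for ci, ch in enumerate(CHANNELS):
        df[ch] = series.values[ci]
    _atomic_write_text(path, df.to_csv(index=False))


def write_cycle(cycle: NormalizedCycle, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"cycle_pos": np.arange(N_CYCLE_POINTS)})
    for ci, ch in enumerate(CHANNELS):
        df[ch] = cycle.matrix[ci]
    _atomic_write_text(path, df.to_csv(index=False))


def read_signature(path: Union[str, Path]) -> np.ndarray:
    """Read a (4, 101) signature matrix from a cycle CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channels {missing}")
    if len(df) != N_CYCLE_POINTS:
        raise ValueError(f"{path}: expected {N_CYCLE_POINTS} rows, got {len(df)}")
    return np.vstack([df[c].to_numpy(float) for c in CHANNELS])


# ---------------------------------------------------------------------------
# manifest

@dataclass
class TrialRecord:
    subject_id: str
    trial_id: str
    label: str
    fps: float
    keypoint_file: str
    resolution: str = ""
    n_frames_total: int = 0
    n_frames_valid: int = 0


@dataclass
class TrialData:
    """A loaded trial: trajectory plus labels (duck-typed like a
    synthetic trial, minus the hidden truth)."""

    trajectory: KeypointTrajectory
    label: str
    subject_id: str
    trial_id: str
    truth: Optional[object] = None


def write_manifest(records: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    ids = [r.trial_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("trial ids must be unique")
    write_json(path, {"trials": [dataclasses.asdict(r) for r in records]})


def read_manifest(path: Union[str, Path]) -> List[TrialRecord]:
    path = Path(path)
    doc = json.loads(path.read_text())
    records = [TrialRecord(**r) for r in doc["trials"]]
    ids = [r.trial_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate trial ids")
    base = path.parent
    for r in records:
        if not (base / r.keypoint_file).exists():
            raise FileNotFoundError(f"{path}: missing keypoint file "
                                    f"{r.keypoint_file} for trial {r.trial_id}")
    return records


def load_trials(manifest_path: Union[str, Path]) -> List[TrialData]:
    base = Path(manifest_path).parent
    out = []
    for r in read_manifest(manifest_path):
        traj = read_keypoints(base / r.keypoint_file, fps=r.fps,
                              trial_id=r.trial_id, subject_id=r.subject_id,
                              label=r.label)
        out.append(TrialData(trajectory=traj, label=r.label,
                             subject_id=r.subject_id, trial_id=r.trial_id))
    return out


def export_cohort(trials, outdir: Union[str, Path]) -> Path:
    """Write a synthetic cohort as keypoint CSVs + manifest + hidden truth.

    Returns the manifest path. Hidden ground truth goes to a separate
    ``truth.json`` so tests can read it while the manifest stays blind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    truth = {}
    for t in trials:
        fname = f"{t.trial_id}.csv"
        write_keypoints(t.trajectory, outdir / fname)
        records.append(TrialRecord(
            subject_id=t.subject_id, trial_id=t.trial_id, label=t.label,
            fps=t.trajectory.fps, keypoint_file=fname,
            n_frames_total=t.trajectory.n_frames,
            n_frames_valid=int(t.trajectory.valid.sum())))
        if t.truth is not None:
            truth[t.trial_id] = {"reversed": bool(t.truth.reversed),
                                 "rom_scale": t.truth.rom_scale.tolist()}
    manifest = outdir / "manifest.json"
    write_manifest(records, manifest)
    if truth:
        write_json(outdir / "truth.json", truth)
    return manifest


# ---------------------------------------------------------------------------
# configuration document

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSettings(_Strict):
    n_per_class: int = 40
    rom_scale_sci: float = 0.5
    frame_count_range: Tuple[int, int] = (60, 250)
    fps: float = 50.0
    angle_noise_sd: float = 2.0
    keypoint_noise_sd: float = 3.0
    reversed_fraction: float = 0.3
    timing_jitter_sd: float = 0.02
    walk_speed: float = 1.0
    seed: int = 0

    def to_config(self) -> CohortConfig:
        return CohortConfig(**self.model_dump())


class QcSettings(_Strict):
    k: int = 5
    n_iter: int = 100
    seed: int = 0
    reversal_threshold: float = 0.9
    flip_mode: str = "lr_swap"
    typical_override: Dict[str, int] = {}


class ValidationSettings(_Strict):
    n_permutations: int = 8000
    alpha: float = 0.05
    seed: int = 17


class MlpSettings(_Strict):
    hidden_width: int = 100
    max_iterations: int = 300
    activation: str = "relu"
    alpha: float = 1e-4
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.25
    seed: int = 0

    def to_config(self) -> MlpConfig:
        return MlpConfig(**self.model_dump())


class PipelineConfig(_Strict):
    """Single config document for the whole pipeline (unknown keys rejected)."""

    cohort: CohortSettings = CohortSettings()
    qc: QcSettings = QcSettings()
    validation: ValidationSettings = ValidationSettings()
    mlp: MlpSettings = MlpSettings()
    normalization: str = "linear"
    shap_samples: int = 512
    shap_background: int = 32
    holdout_fraction: float = 0.25
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds from one master seed."""
        c = self.model_copy(deep=True)
        c.seed = seed
        c.cohort.seed = seed
        c.qc.seed = seed + 1
        c.validation.seed = seed + 2
        c.mlp.seed = seed + 3
        return c

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> PipelineConfig:
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**doc)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class ClassQcResult:
    label: str
    model: cycle_qc.ClusterModel
    typical_clusters: set
    reversed_clusters: set
    discarded_clusters: set
    subset1: cycle_qc.SubsetDefinition
    subset2: cycle_qc.SubsetDefinition


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the JSON-ready report."""

    qc: Dict[str, ClassQcResult]
    subset2_cycles: List[NormalizedCycle]
    subset2_labels: List[str]
    centroid_model: phenotyping.CentroidClassifier
    rom: phenotyping.RomComparison
    centroid_metrics: phenotyping.ClassificationMetrics
    mlp_metrics: phenotyping.ClassificationMetrics
    attribution: Optional[AttributionMap]
    windows: List
    validation: Optional[Dict[str, validation_stats.JointValidation]]
    report: Dict


def run_pipeline(trials: Sequence, config: PipelineConfig,
                 reference: Optional[np.ndarray] = None,
                 explain: bool = True) -> PipelineResult:
    """Execute the full analysis on loaded trials.

    Each trial must expose ``trajectory``, ``label``, ``trial_id`` and
    ``subject_id``. Stages: angle extraction -> 101-point normalization ->
    per-class k-means QC with reversed-trial flip correction -> (optional)
    per-joint validation of the healthy subset-2 signature against
    ``reference`` -> centroid phenotyping and ROM comparison -> MLP
    classification with Shapley window attribution.
    """
    # kinematics + normalization
    cycles_by_class: Dict[str, List[NormalizedCycle]] = {}
    for t in trials:
        series = compute_angle_series(t.trajectory)
        cyc = normalize_time(series, method=config.normalization)
        cycles_by_class.setdefault(t.label, []).append(cyc)
    logger.info("normalized %d trials in %d classes",
                sum(map(len, cycles_by_class.values())), len(cycles_by_class))

    # per-class cycle QC
    qc_results: Dict[str, ClassQcResult] = {}
    subset2_cycles: List[NormalizedCycle] = []
    subset2_labels: List[str] = []
    for label in sorted(cycles_by_class):
        cycles = cycles_by_class[label]
        model = cycle_qc.cluster_cycles(cycles, k=config.qc.k,
                                        n_iter=config.qc.n_iter,
                                        seed=config.qc.seed)
        ref_cluster = cycle_qc.select_typical_cluster(
            model, override=config.qc.typical_override.get(label))
        typ, rev, disc = cycle_qc.classify_clusters(
            model, ref_cluster, threshold=config.qc.reversal_threshold)
        s1, s2 = cycle_qc.build_subsets(model, typ, rev)
        qc_results[label] = ClassQcResult(label=label, model=model,
                                          typical_clusters=typ,
                                          reversed_clusters=rev,
                                          discarded_clusters=disc,
                                          subset1=s1, subset2=s2)
        kept = cycle_qc.subset_cycles(model, s2, flip_mode=config.qc.flip_mode)
        subset2_cycles.extend(kept)
        subset2_labels.extend([label] * len(kept))
        logger.info("%s: typical %s, reversed %s, discarded %s; "
                    "subset1 %d, subset2 %d trials", label, sorted(typ),
                    sorted(rev), sorted(disc), len(s1.kept_trials),
                    len(s2.kept_trials))

    # validation against a reference signature (healthy class)
    validation = None
    if reference is not None and "Healthy" in cycles_by_class:
        healthy = [c for c, l in zip(subset2_cycles, subset2_labels)
                   if l == "Healthy"]
        sig = np.mean([c.matrix for c in healthy], axis=0)
        validation = validation_stats.validate_subset(
            sig, reference, n_permutations=config.validation.n_permutations,
            seed=config.validation.seed)

    # phenotyping on a stratified held-out split (same split as the MLP)
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(subset2_cycles))
    labels_arr = np.asarray(subset2_labels)
    tr, te = train_test_split(idx, test_size=config.holdout_fraction,
                              stratify=labels_arr, random_state=config.seed)
    centroid_train = phenotyping.fit_centroids(
        [subset2_cycles[i] for i in tr], [subset2_labels[i] for i in tr])
    y_pred = [phenotyping.classify(centroid_train, subset2_cycles[i]) for i in te]
    centroid_metrics = phenotyping.compute_metrics(labels_arr[te], y_pred)
    centroid_model = phenotyping.fit_centroids(subset2_cycles, subset2_labels)
    rom = phenotyping.rom_comparison(centroid_model, "Healthy", "SCI")

    # supervised classification + attribution
    clf = train_classifier(subset2_cycles, subset2_labels,
                           config.mlp.to_config())
    attribution = None
    windows: List = []
    if explain:
        rng = np.random.default_rng(config.seed + 4)
        bg_idx = rng.choice(len(subset2_cycles),
                            size=min(config.shap_background, len(subset2_cycles)),
                            replace=False)
        background = [subset2_cycles[i] for i in bg_idx]
        sci_first = next(c for c, l in zip(subset2_cycles, subset2_labels)
                         if l == "SCI")
        attribution = shap_attribution(clf, background, sci_first,
                                       n_samples=config.shap_samples,
                                       seed=config.seed + 5)
        windows = extract_windows(attribution)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "subsets": {
            label: {
                "typical_clusters": sorted(r.typical_clusters),
                "reversed_clusters": sorted(r.reversed_clusters),
                "discarded_clusters": sorted(r.discarded_clusters),
                "subset1_n": len(r.subset1.kept_trials),
                "subset2_n": len(r.subset2.kept_trials),
                "flipped_n": len(r.subset2.flipped_trials),
            } for label, r in qc_results.items()
        },
        "rom_comparison": {j: dataclasses.asdict(v)
                           for j, v in rom.per_joint.items()},
        "centroid_metrics": dataclasses.asdict(centroid_metrics),
        "mlp_metrics": dataclasses.asdict(clf.metrics),
        "windows": [dataclasses.asdict(w) for w in windows],
    }
    if validation is not None:
        report["validation"] = {
            j: {"dtw": v.dtw.distance, "p_perm": v.permutation.p_value,
                "r": v.correlation.r, "p_r": v.correlation.p_value}
            for j, v in validation.items()}
    return PipelineResult(qc=qc_results, subset2_cycles=subset2_cycles,
                          subset2_labels=subset2_labels,
                          centroid_model=centroid_model, rom=rom,
                          centroid_metrics=centroid_metrics,
                          mlp_metrics=clf.metrics, attribution=attribution,
                          windows=windows, validation=validation,
                          report=report)


def reference_signature(params: Optional[GaitTemplateParams] = None) -> np.ndarray:
    """Noise-free template signature on the 101-point grid (simulator
    ground-truth reference for validation)."""
    params = params or GaitTemplateParams()
    series = angle_template(params, np.linspace(0, 1, N_CYCLE_POINTS))
    return series.values


def run_synthetic_study(config: PipelineConfig,
                        explain: bool = True) -> Tuple[PipelineResult, Dict]:
    """Generate a synthetic cohort and run the full pipeline against the
    generator's own clean template as reference.

    Returns the pipeline result and a study report extended with
    generator-truth diagnostics (reversed-trial detection precision/recall
    and the ROM reduction implied by the pathology scaling).
    """
    cohort_cfg = config.cohort.to_config()
    trials = generate_cohort(cohort_cfg)
    result = run_pipeline(trials, config,
                          reference=reference_signature(), explain=explain)
    truth_reversed = {t.trial_id for t in trials if t.truth.reversed}
    detected = set()
    for r in result.qc.values():
        detected |= r.subset2.flipped_trials
    tp = len(detected & truth_reversed)
    precision = tp / len(detected) if detected else None
    recall = tp / len(truth_reversed) if truth_reversed else None
    report = dict(result.report)
    report["reversed_detection"] = {
        "n_true": len(truth_reversed), "n_detected": len(detected),
        "precision": precision, "recall": recall,
        "expected_reduction_pct":
            100.0 * (1.0 - float(np.atleast_1d(cohort_cfg.rom_scale_sci)[0])),
    }
    return result, report
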