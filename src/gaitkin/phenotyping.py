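"""Interpretable SCI-vs-healthy gait phenotyping.

A nearest-centroid classifier over normalized cycles (per-class mean
centroids, Euclidean distance on the flattened 4x101 matrices), per-joint
range-of-motion comparison between class centroids, and confusion-matrix
classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .kinematics import CHANNELS, NormalizedCycle


@dataclass
class CentroidClassifier:
    """Per-class mean-centroid classifier ("k-means classifier" usage)."""

    class_centroids: Dict[str, np.ndarray]  # label -> (4, 101)
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if len(self.class_centroids) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def labels(self) -> List[str]:
        return sorted(self.class_centroids)


@dataclass
class JointRom:
    rom_reference: float
    rom_case: float
    reduction_pct: float
    max_flexion_diff: float


@dataclass
class RomComparison:
    """Per-joint ROM reduction of the case class relative to the reference."""

    reference_label: str
    case_label: str
    per_joint: Dict[str, JointRom]


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]


def fit_centroids(cycles: Sequence[NormalizedCycle],
                  labels: Sequence[str]) -> CentroidClassifier:
    """Element-wise mean matrix per class."""
    if len(cycles) != len(labels):
        raise ValueError("cycles and labels must have equal length")
    by_class: Dict[str, List[np.ndarray]] = {}
    for cyc, lab in zip(cycles, labels):
        by_class.setdefault(lab, []).append(cyc.matrix)
    centroids = {lab: np.mean(np.stack(mats), axis=0)
                 for lab, mats in by_class.items()}
    return CentroidClassifier(class_centroids=centroids)


def classify(model: CentroidClassifier, cycle: NormalizedCycle) -> str:
    """Label of the nearest centroid; ties break to the first sorted label."""
    best_label, best_d = None, np.inf
    for lab in model.labels:  # sorted: deterministic tie-break
        d = float(np.linalg.norm(cycle.matrix - model.class_centroids[lab]))
        if d < best_d:
            best_label, best_d = lab, d
    return best_label


def rom_comparison(model: CentroidClassifier, reference_label: str,
                   case_label: str) -> RomComparison:
    """Per-joint ROM and peak-flexion differences between class centroids.

    ROM is max - min of the centroid time series per joint;
    ``reduction_pct = 100 * (ROM_ref - ROM_case) / ROM_ref`` and
    ``max_flexion_diff = max(ref) - max(case)`` (degrees).
    """
    for lab in (reference_label, case_label):
        if lab not in model.class_centroids:
            raise KeyError(f"label {lab!r} not fitted")
    ref = model.class_centroids[reference_label]
    case = model.class_centroids[case_label]
    per_joint: Dict[str, JointRom] = {}
    for ci, joint in enumerate(CHANNELS):
        rom_ref = float(ref[ci].max() - ref[ci].min())
        rom_case = float(case[ci].max() - case[ci].min())
        if rom_ref <= 0.0:
            raise ValueError(f"zero reference ROM for joint {joint}")
        per_joint[joint] = JointRom(
            rom_reference=rom_ref,
            rom_case=rom_case,
            reduction_pct=100.0 * (rom_ref - rom_case) / rom_ref,
            max_flexion_diff=float(ref[ci].max() - case[ci].max()),
        )
    return RomComparison(reference_label=reference_label,
                         case_label=case_label, per_joint=per_joint)


def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str],
                    positive_label: str = "SCI") -> ClassificationMetrics:
    """Confusion-matrix metrics; undefined ratios are None, never 0."""
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal non-zero length")
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    tp = int(np.sum((yt == positive_label) & (yp == positive_label)))
    fn = int(np.sum((yt == positive_label) & (yp != positive_label)))
    fp = int(np.sum((yt != positive_label) & (yp == positive_label)))
    tn = int(np.sum((yt != positive_label) & (yp != positive_label)))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if precision is None or recall is None or (precision + recall) == 0.0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassificationMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        precision=precision, recall=recall,
        specificity=ratio(tn, tn + fp), f1=f1)
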