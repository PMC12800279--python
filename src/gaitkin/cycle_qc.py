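"""Clustering-based gait-cycle quality control.

Normalized cycles are clustered with k-means (k-means++ seeding) on their
flattened 4x101 matrices; the representative ("typical") cluster is
identified, clusters that are left/right-mirrored copies of it (recorded
while the subject walked in the opposite direction) are detected and
their trials flip-corrected, and two analysis subsets are built: subset 1
holds only the typical clusters, subset 2 additionally merges the
flip-corrected reversed trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .kinematics import CHANNELS, NormalizedCycle

#: Channel index permutation realizing a left/right swap.
_LR_SWAP = [CHANNELS.index(c) for c in ("RHip", "LHip", "RKnee", "LKnee")]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, 4, 101)
    assignments: Dict[str, int]  # trial_id -> cluster id
    inertia: float
    seed: int
    n_iter: int
    cycles: List[NormalizedCycle] = field(default_factory=list, repr=False)

    def members(self, cluster_id: int) -> List[str]:
        return [t for t, c in self.assignments.items() if c == cluster_id]

    def size(self, cluster_id: int) -> int:
        return sum(1 for c in self.assignments.values() if c == cluster_id)


@dataclass
class SubsetDefinition:
    """Filtered trial subset with provenance of every keep/flip decision."""

    kept_trials: Set[str]
    flipped_trials: Set[str]
    provenance: Dict[str, Dict[str, object]]

    def __post_init__(self) -> None:
        if not self.flipped_trials <= self.kept_trials:
            raise ValueError("flipped trials must be a subset of kept trials")


def cluster_cycles(cycles: Sequence[NormalizedCycle], k: int = 5,
                   n_iter: int = 100, seed: int = 0) -> ClusterModel:
    """k-means over flattened cycles (Euclidean distance, k-means++ seeding).

    Channels are not z-scored: all four share degree units. Deterministic
    given ``seed``.
    """
    cycles = list(cycles)
    if len(cycles) < k:
        raise ValueError(f"need at least k={k} cycles, got {len(cycles)}")
    ids = [c.trial_id for c in cycles]
    if len(set(ids)) != len(ids):
        raise ValueError("cycles must carry unique trial_ids")
    X = np.stack([c.flat() for c in cycles])
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=n_iter,
                random_state=seed)
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_.reshape(k, len(CHANNELS), -1)
    return ClusterModel(k=k, centroids=centroids,
                        assignments=dict(zip(ids, labels.tolist())),
                        inertia=float(km.inertia_), seed=seed,
                        n_iter=n_iter, cycles=cycles)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _swap_lr(matrix: np.ndarray) -> np.ndarray:
    return matrix[_LR_SWAP]


def detect_reversed_clusters(model: ClusterModel, reference_cluster: int,
                             threshold: float = 0.9) -> Set[int]:
    """Clusters whose centroid is a left/right mirror of the reference.

    A cluster is flagged when its L/R-swapped centroid correlates with the
    reference centroid above ``threshold`` and above its unswapped
    correlation.
    """
    if not 0 <= reference_cluster < model.k:
        raise ValueError(f"invalid reference cluster {reference_cluster}")
    ref = model.centroids[reference_cluster]
    out: Set[int] = set()
    for c in range(model.k):
        if c == reference_cluster:
            continue
        plain = _corr(model.centroids[c], ref)
        swapped = _corr(_swap_lr(model.centroids[c]), ref)
        if swapped > threshold and swapped > plain:
            out.add(c)
    return out


def flip_trial(cycle: NormalizedCycle, mode: str = "lr_swap") -> NormalizedCycle:
    """Correct a direction-reversed trial.

    Default ``lr_swap`` exchanges LHip<->RHip and LKnee<->RKnee, leaving the
    time axis untouched; ``time_reverse`` additionally flips the time axis
    (provided because the recording artifact is also describable as a
    time-reversed apparent cycle).
    """
    if mode == "lr_swap":
        return replace(cycle, matrix=_swap_lr(cycle.matrix))
    if mode == "time_reverse":
        return replace(cycle, matrix=_swap_lr(cycle.matrix)[:, ::-1].copy())
    raise ValueError(f"unknown flip mode {mode!r}")


def select_typical_cluster(model: ClusterModel,
                           override: Optional[int] = None) -> int:
    """Pick the cluster with the clearest gait signal.

    Default heuristic: maximize (summed channel ROM of the centroid) x
    (membership size), a proxy for a large, clearly articulated cluster.
    An explicit ``override`` id is returned verbatim. The choice is a
    documented heuristic — inspect centroids before trusting it.
    """
    if override is not None:
        if not 0 <= override < model.k:
            raise ValueError(f"invalid cluster override {override}")
        return int(override)
    scores = []
    for c in range(model.k):
        rom = float(np.sum(model.centroids[c].max(axis=1)
                           - model.centroids[c].min(axis=1)))
        scores.append(rom * model.size(c))
    return int(np.argmax(scores))


def classify_clusters(model: ClusterModel, reference_cluster: int,
                      threshold: float = 0.9,
                      majority_orientation: bool = True,
                      ) -> Tuple[Set[int], Set[int], Set[int]]:
    """Partition clusters into (typical, reversed, discarded) sets.

    Typical: unswapped centroid correlation with the reference exceeds
    ``threshold`` (the reference itself included); reversed: per
    :func:`detect_reversed_clusters`; everything else is discarded as
    noise/artifact.

    With ``majority_orientation`` (default), if the flagged-reversed
    clusters hold more trials than the typical ones, the two roles are
    swapped: a mirrored cluster can win the size/ROM reference heuristic,
    but as long as most trials were recorded in the usual direction the
    majority orientation defines "typical".
    """
    reversed_ = detect_reversed_clusters(model, reference_cluster, threshold)
    typical: Set[int] = {reference_cluster}
    for c in range(model.k):
        if c == reference_cluster or c in reversed_:
            continue
        if _corr(model.centroids[c], model.centroids[reference_cluster]) > threshold:
            typical.add(c)
    if majority_orientation:
        n_typ = sum(model.size(c) for c in typical)
        n_rev = sum(model.size(c) for c in reversed_)
        if n_rev > n_typ:
            typical, reversed_ = reversed_, typical
    discarded = set(range(model.k)) - typical - reversed_
    return typical, reversed_, discarded


def build_subsets(model: ClusterModel, typical_clusters: Iterable[int],
                  reversed_clusters: Iterable[int],
                  ) -> Tuple[SubsetDefinition, SubsetDefinition]:
    """Subset 1 = typical clusters; subset 2 = subset 1 + flipped reversed."""
    typical = set(typical_clusters)
    rev = set(reversed_clusters)
    if typical & rev:
        raise ValueError("typical and reversed cluster sets must be disjoint")
    for c in typical | rev:
        if not 0 <= c < model.k:
            raise ValueError(f"invalid cluster id {c}")
    prov1: Dict[str, Dict[str, object]] = {}
    prov2: Dict[str, Dict[str, object]] = {}
    kept1: Set[str] = set()
    flipped: Set[str] = set()
    for trial, c in model.assignments.items():
        if c in typical:
            kept1.add(trial)
            prov1[trial] = prov2[trial] = {"cluster": c, "action": "keep"}
        elif c in rev:
            flipped.add(trial)
            prov2[trial] = {"cluster": c, "action": "flip"}
    subset1 = SubsetDefinition(kept_trials=set(kept1), flipped_trials=set(),
                               provenance=prov1)
    subset2 = SubsetDefinition(kept_trials=kept1 | flipped,
                               flipped_trials=flipped, provenance=prov2)
    return subset1, subset2


def subset_cycles(model: ClusterModel, subset: SubsetDefinition,
                  flip_mode: str = "lr_swap") -> List[NormalizedCycle]:
    """Materialize a subset: kept cycles, with reversed trials flip-corrected."""
    by_id = {c.trial_id: c for c in model.cycles}
    out: List[NormalizedCycle] = []
    for trial in sorted(subset.kept_trials):
        cyc = by_id[trial]
        if trial in subset.flipped_trials:
            cyc = flip_trial(cyc, mode=flip_mode)
        out.append(cyc)
    return out
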