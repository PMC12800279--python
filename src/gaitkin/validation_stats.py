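"""Similarity statistics between angle signatures and a reference.

Implements dynamic time warping (classic unconstrained DP recurrence with
path backtracking), a shuffle-based permutation test of the observed DTW
distance, and Pearson correlation, plus a per-joint validation table for
comparing pipeline-derived signatures against a reference trajectory
(e.g., motion-capture joint angles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .kinematics import CHANNELS, N_CYCLE_POINTS


@dataclass
class DTWResult:
    """Unnormalized DTW distance and its optimal warping path."""

    distance: float
    path: List[Tuple[int, int]]


@dataclass
class PermutationTestResult:
    observed: float
    null_distances: np.ndarray
    p_value: float
    n_permutations: int
    seed: int

    def reject(self, alpha: float = 0.05) -> bool:
        """Significant similarity at level alpha (alpha <= 0.05 advised)."""
        return self.p_value < alpha


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def _as_2d(x: Sequence) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("sequences must be 1-D or (n, d)")
    return a


def _pointwise_cost(xi: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|x_i - y_j| for univariate, Euclidean norm for multivariate."""
    d = Y - xi
    if d.shape[-1] == 1:
        return np.abs(d[..., 0])
    return np.linalg.norm(d, axis=-1)


def dtw_distance(x: Sequence, y: Sequence) -> DTWResult:
    """Dynamic-programming DTW with steps {(i-1,j-1), (i-1,j), (i,j-1)}.

    Pointwise distance is the absolute difference for univariate input and
    the Euclidean distance for multivariate input; no window constraint,
    no normalization. The optimal path is recovered by backtracking and
    runs from (0, 0) to (n-1, m-1) with nondecreasing unit steps.
    """
    X = _as_2d(x)
    Y = _as_2d(y)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch between sequences")
    n, m = X.shape[0], Y.shape[0]
    cost = np.empty((n, m))
    for i in range(n):
        cost[i] = _pointwise_cost(X[i], Y)
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            D[i, j] = cost[i, j] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            moves = ((D[i - 1, j - 1], i - 1, j - 1),
                     (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(moves, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return DTWResult(distance=float(D[n - 1, m - 1]), path=path)


def _dtw_distance_batch(x: np.ndarray, Ys: np.ndarray) -> np.ndarray:
    """DTW distances of one query against a batch of comparators.

    ``x``: (n, d); ``Ys``: (B, m, d). Same recurrence as
    :func:`dtw_distance`, vectorized across the batch axis (used for the
    permutation null); cross-checked against the single-pair DP in tests.
    """
    n, d = x.shape
    B, m, _ = Ys.shape
    prev = np.empty((B, m))
    prev[:, :] = np.cumsum(_pointwise_cost(x[0], Ys), axis=1)
    for i in range(1, n):
        c = _pointwise_cost(x[i], Ys)  # (B, m)
        cur = np.empty((B, m))
        cur[:, 0] = prev[:, 0] + c[:, 0]
        for j in range(1, m):
            best = np.minimum(np.minimum(prev[:, j - 1], prev[:, j]), cur[:, j - 1])
            cur[:, j] = c[:, j] + best
        prev = cur
    return prev[:, -1]


def dtw_permutation_test(x: Sequence, y: Sequence, n_permutations: int = 8000,
                         seed: int = 0, smoothing: str = "none",
                         ) -> PermutationTestResult:
    """Shuffle-based significance of the observed DTW distance.

    The comparator series ``y`` is randomly re-ordered in time (jointly
    across channels) ``n_permutations`` times; the p-value is the fraction
    of null distances at or below the observed one,
    ``p = (1/N) sum I(D_k <= D_obs)``. Small p means the two series are
    more similar than chance re-orderings allow. The literal estimator can
    return p = 0; ``smoothing='plus_one'`` uses (1 + sum I)/(1 + N)
    instead.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = _as_2d(x)
    Y = _as_2d(y)
    if X.shape[0] < 3 or Y.shape[0] < 3:
        raise ValueError("sequences must have length >= 3")
    observed = dtw_distance(X, Y).distance
    rng = np.random.default_rng(seed)
    m = Y.shape[0]
    perms = np.argsort(rng.random((n_permutations, m)), axis=1)
    null = _dtw_distance_batch(X, Y[perms])
    hits = int(np.sum(null <= observed + 1e-12))
    if smoothing == "plus_one":
        p = (1 + hits) / (1 + n_permutations)
    elif smoothing == "none":
        p = hits / n_permutations
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return PermutationTestResult(observed=observed, null_distances=null,
                                 p_value=float(p),
                                 n_permutations=n_permutations, seed=seed)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value (n-2 dof)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ValueError("need n >= 3 samples")
    if np.var(xa) == 0.0 or np.var(ya) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=int(xa.size))


@dataclass
class JointValidation:
    joint: str
    dtw: DTWResult
    permutation: PermutationTestResult
    correlation: CorrelationResult


def validate_subset(signatures: np.ndarray, reference: np.ndarray,
                    n_permutations: int = 8000, seed: int = 0,
                    ) -> Dict[str, JointValidation]:
    """Per-joint DTW + permutation + Pearson validation table.

    ``signatures`` and ``reference`` are (4, 101) matrices (channel order
    LHip, RHip, LKnee, RKnee) on the cycle grid — typically a subset's
    per-joint mean/centroid signature and a reference trajectory.
    """
    sig = np.asarray(signatures, dtype=float)
    ref = np.asarray(reference, dtype=float)
    expected = (len(CHANNELS), N_CYCLE_POINTS)
    if sig.shape != expected or ref.shape != expected:
        raise ValueError(f"signatures and reference must both be {expected}")
    out: Dict[str, JointValidation] = {}
    for ci, joint in enumerate(CHANNELS):
        out[joint] = JointValidation(
            joint=joint,
            dtw=dtw_distance(sig[ci], ref[ci]),
            permutation=dtw_permutation_test(sig[ci], ref[ci],
                                             n_permutations=n_permutations,
                                             seed=seed + ci),
            correlation=pearson(sig[ci], ref[ci]),
        )
    return out


def validation_table(results: Dict[str, JointValidation]) -> "pandas.DataFrame":
    """Tabular view (joint, dtw, p_perm, r, p_r) of a validation run."""
    import pandas as pd

    rows = [{"joint": j, "dtw": v.dtw.distance,
             "p_perm": v.permutation.p_value,
             "r": v.correlation.r, "p_r": v.correlation.p_value}
            for j, v in results.items()]
    return pd.DataFrame(rows)
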