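"""Supervised discrimination with Shapley-value time-window attribution.

A small feed-forward network (one ReLU hidden layer, Adam, trained on the
flattened 4x101 cycle vectors) separates SCI from healthy cycles; a
permutation-sampling Shapley estimator attributes the predicted SCI
probability to each of the 404 (channel, timepoint) features, and
contiguous high-|attribution| runs become "significant window" bounding
boxes on the gait cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .kinematics import CHANNELS, N_CYCLE_POINTS, NormalizedCycle
from .phenotyping import ClassificationMetrics, compute_metrics

N_FEATURES = len(CHANNELS) * N_CYCLE_POINTS


@dataclass(frozen=True)
class MlpConfig:
    """Network and training settings.

    One hidden layer of ``hidden_width`` rectifier units, Adam optimizer,
    at most ``max_iterations`` epochs. Regularization is an L2 weight
    penalty ``alpha`` (the backend network has no dropout layer).
    """

    hidden_width: int = 100
    max_iterations: int = 300
    activation: str = "relu"
    alpha: float = 1e-4
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class TrainedClassifier:
    model: MLPClassifier
    positive_label: str
    metrics: ClassificationMetrics
    config: MlpConfig

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) for flattened cycle rows."""
        col = list(self.model.classes_).index(self.positive_label)
        return self.model.predict_proba(np.atleast_2d(X))[:, col]


@dataclass
class AttributionMap:
    """Signed per-(channel, timepoint) Shapley attributions.

    ``baseline`` is the mean model output over the drawn background
    samples; by the telescoping construction,
    ``baseline + values.sum() == model output at the instance`` up to
    floating point, for any ``n_samples``.
    """

    values: np.ndarray  # (4, 101)
    baseline: float
    model_output: float
    n_samples: int
    seed: int


@dataclass
class SignificantWindow:
    channel: str
    start: int  # cycle percent, inclusive
    end: int  # cycle percent, inclusive
    sign: str  # "increases-SCI-probability" | "decreases-SCI-probability"
    mean_attribution: float
    mass: float  # sum of |attribution| in the window (ranking key)


def _stack(cycles: Sequence[NormalizedCycle]) -> np.ndarray:
    return np.stack([c.flat() for c in cycles])


def train_classifier(cycles: Sequence[NormalizedCycle], labels: Sequence[str],
                     config: Optional[MlpConfig] = None,
                     positive_label: str = "SCI") -> TrainedClassifier:
    """Train on a stratified split and report held-out metrics.

    Deterministic given ``config.seed`` (split and weight initialization
    both derive from it).
    """
    config = config or MlpConfig()
    X = _stack(cycles)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.holdout_fraction, stratify=y,
        random_state=config.seed)
    model = MLPClassifier(hidden_layer_sizes=(config.hidden_width,),
                          activation=config.activation, solver="adam",
                          alpha=config.alpha,
                          learning_rate_init=config.learning_rate,
                          max_iter=config.max_iterations,
                          random_state=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_tr, y_tr)
    metrics = compute_metrics(y_te, model.predict(X_te),
                              positive_label=positive_label)
    return TrainedClassifier(model=model, positive_label=positive_label,
                             metrics=metrics, config=config)


def shap_attribution(clf: TrainedClassifier,
                     background: Sequence[NormalizedCycle],
                     instance: NormalizedCycle,
                     n_samples: int = 512, seed: int = 0,
                     chunk: int = 8) -> AttributionMap:
    """Permutation-sampling Shapley attribution of the SCI probability.

    For each of ``n_samples`` Monte-Carlo draws, a background cycle and a
    random feature ordering are sampled; features are switched one at a
    time from the background value to the instance value in that order and
    the marginal output changes are accumulated per feature. Marginal
    contributions telescope, so additivity
    (baseline + sum(values) = output) holds exactly for every sample
    count, while per-feature values converge to the Shapley values with
    uniform-random coalitions imputed from the background distribution.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    rng = np.random.default_rng(seed)
    bg = _stack(background)
    x = instance.flat()
    phi = np.zeros(N_FEATURES)
    baseline_acc = 0.0
    fx = None
    steps = np.arange(N_FEATURES + 1)[:, None]  # (405, 1)
    for start in range(0, n_samples, chunk):
        b = min(chunk, n_samples - start)
        rows = []
        orders = []
        for _ in range(b):
            z = bg[rng.integers(0, bg.shape[0])]
            order = rng.permutation(N_FEATURES)
            pos = np.empty(N_FEATURES, dtype=int)
            pos[order] = np.arange(N_FEATURES)
            mask = pos[None, :] < steps  # (405, 404): replaced-so-far sets
            rows.append(np.where(mask, x[None, :], z[None, :]))
            orders.append(order)
        preds = clf.predict_proba_positive(np.concatenate(rows))
        preds = preds.reshape(b, N_FEATURES + 1)
        for k in range(b):
            deltas = np.diff(preds[k])
            phi[orders[k]] += deltas
            baseline_acc += preds[k, 0]
            fx = preds[k, -1]  # full-instance row, identical across samples
    phi /= n_samples
    baseline = baseline_acc / n_samples
    return AttributionMap(values=phi.reshape(len(CHANNELS), N_CYCLE_POINTS),
                          baseline=float(baseline), model_output=float(fx),
                          n_samples=n_samples, seed=seed)


def extract_windows(amap: AttributionMap,
                    threshold: Optional[float] = None) -> List[SignificantWindow]:
    """Merge supra-threshold timepoints into per-channel windows.

    Default threshold: mean + 2*SD of |attribution| over all 404 features.
    Windows are returned sorted by descending attribution mass; the sign is
    the sign of the mean attribution within the window.
    """
    v = amap.values
    if not np.all(np.isfinite(v)):
        raise ValueError("attribution map contains non-finite values")
    absv = np.abs(v)
    if threshold is None:
        threshold = float(absv.mean() + 2.0 * absv.std())
    windows: List[SignificantWindow] = []
    for ci, channel in enumerate(CHANNELS):
        above = absv[ci] > threshold
        if not above.any():
            continue
        # contiguous runs of supra-threshold timepoints
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            seg = v[ci, s:e]
            mean_attr = float(seg.mean())
            windows.append(SignificantWindow(
                channel=channel, start=int(s), end=int(e - 1),
                sign=("increases-SCI-probability" if mean_attr > 0
                      else "decreases-SCI-probability"),
                mean_attribution=mean_attr,
                mass=float(np.abs(seg).sum())))
    windows.sort(key=lambda w: w.mass, reverse=True)
    return windows
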