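import numpy as np
import pytest

from gaitkin.kinematics import CHANNELS, NormalizedCycle
from gaitkin.synthetic_gait import GaitTemplateParams, SkeletonGeometry


def random_template(rng: np.random.Generator) -> GaitTemplateParams:
    """A random physiologically shaped template, safely inside (0, 180) deg."""
    hip_mean = rng.uniform(20.0, 35.0)
    return GaitTemplateParams(
        hip_mean=hip_mean,
        hip_amp=rng.uniform(3.0, hip_mean - 5.0),
        hip_phase=rng.uniform(0.0, 1.0) % 1.0,
        knee_bump1_amp=rng.uniform(5.0, 25.0),
        knee_bump1_center=rng.uniform(0.05, 0.30),
        knee_bump1_width=rng.uniform(0.05, 0.12),
        knee_bump2_amp=rng.uniform(30.0, 70.0),
        knee_bump2_center=rng.uniform(0.55, 0.85),
        knee_bump2_width=rng.uniform(0.06, 0.14),
    )


def make_cycle(matrix: np.ndarray, trial_id: str = "t0",
               label: str = "unknown") -> NormalizedCycle:
    return NormalizedCycle(np.asarray(matrix, dtype=float),
                           trial_id=trial_id, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom():
    return SkeletonGeometry()


@pytest.fixture
def default_params():
    return GaitTemplateParams()
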