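import numpy as np
import pytest

from baciveg.config import AnalysisConfig
from baciveg.synthetic import SceneSpec, generate_stack, make_truth


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def small_spec():
    """Tiny noiseless cloud-free scene spanning both epochs."""
    return SceneSpec(
        width=4,
        height=4,
        years=(1984, 2012),
        obs_per_year=8,
        declaration_year=1993,
        seed=7,
    )


@pytest.fixture
def small_truth(small_spec):
    return make_truth(
        (small_spec.height, small_spec.width),
        slope_after={"brownest": 0.01, "driest": 0.004},
        slope_before={"brownest": -0.002, "driest": 0.001},
    )


@pytest.fixture
def small_stack(small_spec, small_truth):
    return generate_stack(small_spec, small_truth)


def brute_force_sen(x, y):
    """Independent oracle: exhaustive median of all pairwise slopes."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] != x[i]:
                slopes.append((y[j] - y[i]) / (x[j] - x[i]))
    return float(np.median(slopes))
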