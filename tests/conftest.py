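import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netretest import ThresholdedGraph

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def graph_from_weights(W, threshold=0.0, **meta) -> ThresholdedGraph:
    """Build a ThresholdedGraph directly from a symmetric weight matrix."""
    W = np.asarray(W, dtype=float)
    return ThresholdedGraph(weights=W, support=W != 0, threshold=threshold, **meta)


@pytest.fixture
def triangle():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = W[0, 2] = W[2, 0] = W[1, 2] = W[2, 1] = 0.5
    return graph_from_weights(W)


@pytest.fixture
def path3():
    # a - b - c
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.5
    return graph_from_weights(W)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
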