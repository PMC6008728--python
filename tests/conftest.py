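import numpy as np
import pytest

from confex import io as cio
from confex import msm


@pytest.fixture(scope="session")
def experimental():
    """Packaged experimental (T, kex, pE) series at 1-20.4 °C."""
    return cio.experimental_rates()


@pytest.fixture(scope="session")
def chain3_model():
    """Symmetric 3-state chain A-I-B (reversible by construction)."""
    c = np.array([[80, 20, 0], [20, 60, 20], [0, 20, 80]])
    return msm.transition_matrix(c, reversible=True, lag_time=1.0)


def two_state_model(p01: float, p10: float, lag_time: float = 1.0) -> msm.TransitionModel:
    """Exact two-state model built from large synthetic counts."""
    t = np.array([[1 - p01, p01], [p10, 1 - p10]])
    pi = np.array([p10, p01]) / (p01 + p10)
    c = np.rint(t * pi[:, None] * 1e9).astype(np.int64)
    return msm.transition_matrix(c, reversible=True, lag_time=lag_time)
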