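import numpy as np
import pytest

from laminar.circuit import MicrocircuitWeights
from laminar.plasticity import FeedbackSpec, make_feedback


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_weights():
    """Small random circuit (symmetric feedback) for oracle checks."""
    w = MicrocircuitWeights.initialize(
        n_in=6, n_l4=5, n_l23=7, n_l5=4, n_td=3, seed=1
    )
    make_feedback(w, FeedbackSpec("symmetric"))
    return w


@pytest.fixture
def random_step(small_weights, rng):
    """A forward step on random inputs through the small circuit."""
    from laminar.circuit import forward_step

    x_prev = rng.random(6)
    x_t = rng.random(6)
    i_td = rng.random(3)
    return forward_step(x_prev, x_t, i_td, small_weights), (x_prev, x_t, i_td)
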