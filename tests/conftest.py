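import numpy as np
import pytest

from predadapt import NetworkParams, init_weights


@pytest.fixture
def toy_params() -> NetworkParams:
    """A 4-3-2 network small enough for hand-traceable dynamics."""
    return NetworkParams(
        n_input=4, n_hidden=3, n_output=2, T_settle=12, t_clamp=8, predictor_window=5, seed=7
    )


@pytest.fixture
def toy_weights(toy_params):
    return init_weights(toy_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
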