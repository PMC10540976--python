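import numpy as np
import pytest

from mirnn.model import Dimensions, ExperimentalCondition, MiRNN, init_params


@pytest.fixture
def small_dims() -> Dimensions:
    return Dimensions(n_s=2, n_m=1, n_u=1, n_h=3)


@pytest.fixture
def small_params(small_dims):
    return init_params(small_dims, seed=7)


@pytest.fixture
def small_condition(small_dims):
    rng = np.random.default_rng(3)
    return ExperimentalCondition(
        s0=np.array([0.6, 0.4]),
        m0=np.array([0.2]),
        controls=rng.uniform(0, 1, size=(5, small_dims.n_u)),
        times=np.arange(5.0),
        condition_id="c0",
    )


@pytest.fixture
def small_model(small_dims) -> MiRNN:
    return MiRNN(small_dims)
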