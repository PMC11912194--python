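import numpy as np
import pytest

from mtsm import ToyParams, toy_macro_aggregation, toy_micro_matrix


@pytest.fixture
def symmetric_2x2():
    """A plainly Markovian two-state matrix with stationary (1/2, 1/2)."""
    from mtsm import validate_stochastic

    return validate_stochastic([[0.75, 0.25], [0.25, 0.75]])


@pytest.fixture(params=[(0.1, 0.1), (0.5, 0.1), (0.1, 0.5), (0.02, 0.4)])
def toy_params(request):
    h, k = request.param
    return ToyParams(h=h, k=k)


@pytest.fixture
def toy_weak():
    """Weakly non-Markovian lumping, h/k = 1."""
    return ToyParams(h=0.1, k=0.1)


@pytest.fixture
def toy_strong():
    """Strongly non-Markovian lumping, h/k = 5."""
    return ToyParams(h=0.5, k=0.1)


@pytest.fixture
def toy_markovian():
    """Near-Markovian lumping, h/k = 0.2."""
    return ToyParams(h=0.1, k=0.5)


@pytest.fixture
def toy_setup(toy_weak):
    t = toy_micro_matrix(toy_weak)
    return toy_weak, t, toy_macro_aggregation(toy_weak)


def random_stochastic(rng, n):
    """Random dense column-stochastic matrix (test helper)."""
    M = rng.random((n, n)) + 0.05
    return M / M.sum(axis=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
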