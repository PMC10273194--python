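import numpy as np
import pytest


def random_censored_instance(rng, n_max=50, censor_frac=0.3, ties=False):
    """A small random survival instance with ~30% censoring."""
    n = int(rng.integers(5, n_max + 1))
    time = rng.exponential(1.0, n)
    if ties:
        time = np.round(time, 1) + 0.05  # induce tied observed times
    event = (rng.random(n) >= censor_frac).astype(int)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    scores = rng.standard_normal(n)
    if ties:
        scores = np.round(scores, 1)
    return scores, time, event


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def linear_dataset():
    from survselect import gen_linear

    return gen_linear(300, 20, 5, seed=11)
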