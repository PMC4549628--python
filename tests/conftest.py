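import numpy as np
import pytest

import dualsys as ds


@pytest.fixture(scope="session")
def config():
    return ds.TaskConfig()


@pytest.fixture(scope="session")
def small_config():
    """One block of 42 trials -- enough structure, fast to simulate."""
    return ds.TaskConfig(n_blocks=1)


@pytest.fixture(scope="session")
def nonrep_log(config):
    """A full session of the scripted minimum-error agent."""
    return ds.run_session(ds.NonRepeatingAgent(seed=1), config, seed=0)


@pytest.fixture(scope="session")
def ec_subject():
    """One synthetic entropy-coordination subject (ground truth + log)."""
    gt = ds.GroundTruth(
        "entropy_coordination",
        dict(alpha=0.4, beta=8.0, N=7, epsilon=0.01, lambda1=10.0, lambda2=3.0,
             sigma=1.5),
        seed=3,
    )
    return gt, ds.generate_subject(gt)


def positive_store(params=None, items=()):
    """A memory store holding the given (s, a, r) items, oldest pushed first."""
    params = params or ds.BWMParams(N=5, epsilon=0.0, theta=1.0)
    store = ds.MemoryStore(params)
    for s, a, r in items:
        ds.push_and_decay(store, ds.encode_item(s, a, r))
    return store


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
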