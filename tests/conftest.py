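import numpy as np
import pytest

from intermotion.synthetic import GeneratorConfig, simulate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_cohort():
    """Three 1-h individuals with ground truth, shared across tests."""
    trajs, truths = [], []
    for i in range(3):
        cfg = GeneratorConfig(duration=3600.0, seed=1000 + i)
        t, tr = simulate_trajectory(cfg, individual_id=f"ind{i}", return_truth=True)
        trajs.append(t)
        truths.append(tr)
    return trajs, truths
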