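import numpy as np
import pytest

from dacrank import ModelSpec, generate_dataset, synthetic_expert_panel, uniform, normal


@pytest.fixture(scope="session")
def std_normal_data():
    """n = 100 standard-normal draws, the canonical simulation dataset."""
    return generate_dataset(n=100, mu=0.0, sigma=1.0, seed=1)


@pytest.fixture(scope="session")
def panel():
    """Four synthetic experts: near-truth, biased, overconfident, random."""
    return synthetic_expert_panel(k=4, truth_mu=0.0, seed=7)


@pytest.fixture(scope="session")
def plugin_model():
    return ModelSpec()


@pytest.fixture(scope="session")
def wide_uniform():
    return uniform(-50.0, 50.0)


@pytest.fixture(scope="session")
def wide_normal():
    return normal(0.0, 100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
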