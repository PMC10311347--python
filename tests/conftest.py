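import numpy as np
import pytest

from dtitransfer import FNNConfig, generate_toy_activity_table, init_fnn
from dtitransfer.curation import LabeledCompound


@pytest.fixture(scope="session")
def toy_records():
    return generate_toy_activity_table()


@pytest.fixture
def tiny_config():
    """A small, fast FNN configuration for contract tests."""
    return FNNConfig(input_dim=8, hidden_sizes=(12, 6), epochs=5, batch_size=4, seed=5)


@pytest.fixture
def tiny_data(tiny_config):
    """Linearly separable two-class data in the tiny config's input space."""
    rng = np.random.default_rng(42)
    w = rng.standard_normal(tiny_config.input_dim)
    X = rng.standard_normal((40, tiny_config.input_dim)).astype(np.float32)
    y = (X @ w > 0).astype(np.int64)
    return X, y


@pytest.fixture
def tiny_params(tiny_config):
    return init_fnn(tiny_config)


def make_labeled_pool(n_active: int, n_inactive: int) -> list[LabeledCompound]:
    """A synthetic curated pool with the requested class counts."""
    pool = []
    for i in range(n_active):
        pool.append(LabeledCompound(f"A{i}", "CCO", "kinase", 8.0, "active"))
    for i in range(n_inactive):
        pool.append(LabeledCompound(f"I{i}", "CCN", "kinase", 5.0, "inactive"))
    return pool
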