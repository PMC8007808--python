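import numpy as np
import pytest

from comodule.data import ExpressionMatrix
from comodule.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=300,
        module_sizes=(40, 25),
        n_background=200,
        loading_range=(0.6, 0.9),
        seed=7,
    )
    return generate_dataset(cfg)


def make_expression(values, prefix_s="S", prefix_g="G"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix_s}{i}" for i in range(values.shape[0])],
        [f"{prefix_g}{j}" for j in range(values.shape[1])],
    )
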