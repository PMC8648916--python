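import numpy as np
import pytest

from rknet import AbundanceTable, SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic crossover experiment shared across tests."""
    cfg = SimulationConfig(
        n_k_otus=10, n_r_otus=10, n_neutral_otus=5,
        days=(1, 8, 15, 22, 28, 29, 36, 43, 50),
        depth=5000, seed=42,
    )
    return generate_experiment(cfg)


@pytest.fixture()
def tiny_table():
    values = np.array([[4.0, 1.0, 0.0],
                       [2.0, 2.0, 1.0],
                       [1.0, 3.0, 6.0],
                       [0.0, 4.0, 2.0]])
    return AbundanceTable(values, ["s1", "s2", "s3", "s4"], ["a", "b", "c"], "counts")
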