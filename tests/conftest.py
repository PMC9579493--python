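import numpy as np
import pytest

from motse.datasets import sample_probe
from motse.model import TrainConfig, train_task_model
from motse.synthetic import GeneratorConfig, build_benchmark, generate_molecules

TINY_CFG = TrainConfig(
    hidden_dim=8, predictor_hidden=16, max_epochs=8, batch_size=32, seed=0
)


@pytest.fixture(scope="session")
def bench300():
    """Four counting-task datasets over 300 shared synthetic molecules."""
    return build_benchmark(GeneratorConfig(seed=5), 300)


@pytest.fixture(scope="session")
def probe20():
    """Small probe set drawn from an independent molecule pool."""
    pool = generate_molecules(GeneratorConfig(seed=4242), 60)
    return sample_probe(pool, 20, seed=1, source="synthetic-pool")


@pytest.fixture(scope="session")
def tiny_model(bench300):
    """A small trained NOCount model shared by attribution/mrsa tests."""
    return train_task_model(bench300["NOCount"], TINY_CFG)
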