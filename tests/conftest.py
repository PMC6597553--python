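import numpy as np
import pytest

from trader_dti.benchmarks import get_benchmark
from trader_dti.pipeline import InteractionTable
from trader_dti.similarity import (
    compute_weights,
    drug_similarity_matrix,
    simple_scheme,
    target_similarity_matrix,
)
from trader_dti.synthetic import make_fixture
from trader_dti.trader import TraderConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere10():
    return get_benchmark("sphere", 10)


@pytest.fixture
def quick_config():
    return TraderConfig(
        population_size=20, num_traders=2, max_iterations=50, bounds=(-100.0, 100.0), seed=7
    )


@pytest.fixture(scope="session")
def tiny_world():
    return make_fixture("tiny4x3")


@pytest.fixture(scope="session")
def tiny_matrices(tiny_world):
    """Similarity matrices for the hand-checkable 4x3 world (simple
    match/mismatch alignment scheme so scores stay hand-computable)."""
    drug_sim = drug_similarity_matrix(tiny_world.fingerprints)
    target_sim = target_similarity_matrix(
        tiny_world.sequences, simple_scheme(match=1.0, mismatch=-1.0, gap=1.0)
    )
    return drug_sim, target_sim


@pytest.fixture(scope="session")
def xor_dataset():
    return make_fixture("xor")
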