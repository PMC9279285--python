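import pytest

from cofrac.benchmark import BenchmarkData, simulate_benchmark
from cofrac.synth import SimulationConfig, generate_ground_truth, simulate_elution


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale study design: quick but structurally faithful."""
    return SimulationConfig(
        n_proteins=90, n_complexes=8, n_fractions=64, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_data(small_truth, small_config):
    """(matrices, design) for the small study."""
    return simulate_elution(small_truth, small_config)


@pytest.fixture(scope="session")
def bench() -> BenchmarkData:
    """Default-scale benchmark (500 proteins, 50 complexes, 192 fractions)."""
    return simulate_benchmark(seed=1)
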