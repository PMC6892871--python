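import numpy as np
import pytest

from trioaudit.synthetic_trio import SimulationConfig, TrioSimulator


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=5,
        genome_length=120_000,
        dnm_count=8,
        artifact_count=30,
        shared_artifact_count=3,
        db_artifact_count=2,
    )


@pytest.fixture(scope="session")
def sim_result(small_config):
    """One small simulated family, shared across tests (read-only)."""
    return TrioSimulator(small_config).run()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_reference(rng: np.random.Generator, length: int = 2000, n_chroms: int = 1):
    return {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_chroms)
    }
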