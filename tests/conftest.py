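import numpy as np
import pytest

from enzyclass.config import RunConfig
from enzyclass.pipeline import run_synthetic_benchmark

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(AAS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced trained pipeline shared by the slower integration tests."""
    config = RunConfig(seed=11, min_class_size=20)
    return run_synthetic_benchmark(
        seed=11,
        n_main=3,
        members_per_family=32,
        n_nonenzymes=128,
        config=config,
    )
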