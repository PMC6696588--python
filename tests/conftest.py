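import numpy as np
import pytest

from probeal import synthetic as sy
from probeal.al_engine import run_active_learning
from probeal.pipeline import matrices_from_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset reused across module tests."""
    return sy.generate(sy.SynthConfig(n_compounds=120, rng_seed=7))


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return matrices_from_dataset(small_dataset, "dipeptide")


@pytest.fixture(scope="session")
def short_run(small_matrices):
    """One short curiosity trajectory shared by history-consuming tests."""
    m = small_matrices
    return run_active_learning(
        m.X_pool,
        m.y_pool,
        m.X_ext,
        m.y_ext,
        strategy="curiosity",
        rng_seed=3,
        stop_fraction=0.15,
        weight_interval=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
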