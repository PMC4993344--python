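import numpy as np
import pytest

from comethage.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate cohort shared by read-only tests (do not mutate)."""
    cfg = SimulationConfig(seed=11, n_cpgs=1200)
    betas, sheet, truth = simulate_cohort(cfg)
    return betas, sheet, truth


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        seed=5,
        n_individuals={"HD": 8, "control": 8},
        n_cpgs=400,
        n_modules=2,
        module_sizes=(40, 30),
        n_hd_modules=1,
    )
    betas, sheet, truth = simulate_cohort(cfg)
    return betas, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
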