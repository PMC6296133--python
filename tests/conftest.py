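import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from screenmsm import (
    AgePartition,
    REFERENCE_NONHOMOGENEOUS,
    SimulationConfig,
    fit_mle,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def partition():
    return AgePartition()


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_NONHOMOGENEOUS


@pytest.fixture(scope="session")
def small_cohort():
    """4,000-woman model-faithful cohort at the reference truth."""
    config = SimulationConfig(n_women=4_000, seed=5)
    cohort, truth = simulate_cohort(config)
    return cohort, truth


@pytest.fixture(scope="session")
def mc_cohort():
    """120,000-woman model-faithful cohort at the reference truth, for
    Monte-Carlo cross-checks of formulas against latent ground truth."""
    config = SimulationConfig(n_women=120_000, seed=9)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def recovery_fit():
    """The parameter-recovery study: 50,000 women simulated in model-faithful
    mode at the reference (published) truth, refitted by maximum likelihood
    with left-truncation conditioning.  Shared session-wide because the fit
    is the expensive step."""
    config = SimulationConfig(n_women=50_000, seed=20_260)
    cohort, truth = simulate_cohort(config)
    fit = fit_mle(
        cohort,
        AgePartition(),
        model_kind="nonhomogeneous",
        seed=20_260,
        condition_on_entry=True,
    )
    return cohort, truth, fit


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
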