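import numpy as np
import pytest

from tcrlens.germline import bundled_mini_reference
from tcrlens.simulate import CohortSpec, SpikedCombination, simulate_cohort


@pytest.fixture(scope="session")
def mini_ref():
    return bundled_mini_reference(n_v=20, n_j=13, seed=7)


@pytest.fixture(scope="session")
def small_cohort(mini_ref):
    """4 samples, 60 clones, 800 reads each; error-free."""
    spec = CohortSpec(
        n_cases=2,
        n_controls=2,
        clones_per_sample=60,
        reads_per_sample=800,
        error_rate=0.0,
        seed=11,
    )
    return simulate_cohort(spec, mini_ref)


@pytest.fixture(scope="session")
def spiked_cohort(mini_ref):
    """3v3 cohort with one case-only spiked combination."""
    spec = CohortSpec(
        n_cases=3,
        n_controls=3,
        clones_per_sample=60,
        reads_per_sample=2000,
        error_rate=0.0,
        spiked_combinations=[
            SpikedCombination("TRBVs3", "TRBJs1", "case", 3, 2e-3),
        ],
        seed=5,
    )
    return simulate_cohort(spec, mini_ref)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
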