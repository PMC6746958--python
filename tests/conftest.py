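import numpy as np
import pytest

from collinear_ewas import default_raine_like_spec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (n=812), fixed seed."""
    return generate_cohort(default_raine_like_spec(seed=0))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for correlation-recovery checks (n=100,000)."""
    return generate_cohort(default_raine_like_spec(n_participants=100_000, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
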