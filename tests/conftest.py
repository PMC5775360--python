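import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """Evolved 5.6 kb, 8-taxon synthetic dataset with planted truth."""
    from plastidkit import synthetic_data as sd

    return sd.simulate(sd.small_config(seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """Evolved 20 kb, 8-taxon synthetic dataset at the standard conditions."""
    from plastidkit import synthetic_data as sd

    return sd.simulate(sd.default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, p=(0.315, 0.185, 0.185, 0.315)):
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))
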