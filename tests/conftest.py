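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
def default_cfg():
    from apoescore.simulate import default_config

    return default_config(seed=7)


@pytest.fixture(scope="session")
def study_cohort(default_cfg):
    """One 110+110 cohort drawn at the study's sample sizes."""
    from apoescore.simulate import simulate_cohort

    return simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort (5000/group) for direction-of-effect checks."""
    from apoescore.simulate import default_config, simulate_cohort

    return simulate_cohort(default_config(n_case=5000, n_control=5000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160519)
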