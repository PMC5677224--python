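import pytest

from contextfuse import ClinicalLabeler, load_config
from contextfuse.simulate import generate_cohort


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def labeler(config):
    return ClinicalLabeler(config)


@pytest.fixture(scope="session")
def small_cohort():
    """Six users (one per archetype), seven days, fixed seed."""
    return generate_cohort(6, 7, seed=20210)
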