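import pytest

from immunotriad import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A 60-patient synthetic cohort under default study conditions."""
    return generate_cohort(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort_config():
    return SynthConfig()
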