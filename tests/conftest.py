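import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (10 + 10 treated, 5 saline), seed 42."""
    from petpd.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=42))
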