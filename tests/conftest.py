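import pytest

from sundose.synthetic import generate_cohort, load_fixture


@pytest.fixture(scope="session")
def uvb_series():
    """Packaged hourly UVB intensity series."""
    return load_fixture("intensity")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort + diary at study-condition defaults (seed 1)."""
    return generate_cohort(seed=1)
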