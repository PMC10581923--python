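import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None)
settings.load_profile("ci")

from nutrireq.datasets import load_reference_trial
from nutrireq.synthetic_trial import default_design, generate_trial


@pytest.fixture(scope="session")
def reference_trial():
    return load_reference_trial()


@pytest.fixture(scope="session")
def small_trial():
    """One deterministic synthetic trial shared across I/O-ish tests."""
    return generate_trial(default_design(seed=11))
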