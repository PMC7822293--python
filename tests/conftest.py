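import pytest
from hypothesis import settings

from cleancook import generate_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nepal():
    """Full-scale Nepal-like synthetic parameter set."""
    return generate_fixture(1, "nepal_like")


@pytest.fixture(scope="session")
def minimal():
    """Small frictionless parameter set (full usage, no leakage/spillover)."""
    return generate_fixture(1, "minimal")
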