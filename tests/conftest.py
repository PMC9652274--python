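import pytest

from mitofinish import simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One synthetic truth bundle shared by read-only tests."""
    return simulate_bundle(seed=11, n_deletions=3)


@pytest.fixture(scope="session")
def clean_bundle():
    """A bundle without planted errors (for masking/pipeline tests)."""
    return simulate_bundle(seed=12, n_deletions=0)
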