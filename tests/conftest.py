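import pytest

from wavebio import (load_packaged_frequencies, load_packaged_priors,
                     load_packaged_registry)


@pytest.fixture(scope="session")
def registry():
    return load_packaged_registry()


@pytest.fixture(scope="session")
def freq(registry):
    return load_packaged_frequencies()


@pytest.fixture(scope="session")
def priors():
    return load_packaged_priors()
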