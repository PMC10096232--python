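import pytest

from its_structphylo.synthdata import SynthConfig, generate_family, make_toy_cbc_set


@pytest.fixture(scope="session")
def small_family():
    """One deterministic 6-taxon family with full truth."""
    return generate_family(SynthConfig(n_taxa=6, seed=11))


@pytest.fixture(scope="session")
def toy_cbc():
    return make_toy_cbc_set()
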