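import pytest

from orthoseek.simdata import FamilyConfig, generate_family


@pytest.fixture(scope="session")
def small_family():
    """One deterministic synthetic family with all adversary types."""
    return generate_family(FamilyConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_family():
    """A fast family: fewer species/decoys, short domain."""
    cfg = FamilyConfig(n_species=3, domain_length=120, n_decoys=3, seed=7)
    return generate_family(cfg)
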