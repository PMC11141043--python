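import pytest

from genscore.fixtures import make_library


@pytest.fixture(scope="session")
def library():
    """A deterministic 120-molecule library, all valid."""
    return make_library(120, seed=11, invalid_fraction=0.0)


@pytest.fixture(scope="session")
def mixed_library():
    """A deterministic 100-entry library with exactly 10 invalid SMILES."""
    return make_library(100, seed=5, invalid_fraction=0.1)
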