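import pytest

from chlamyflux.efm import enumerate_efms
from chlamyflux.network import load_core_model


@pytest.fixture(scope="session")
def core_model():
    return load_core_model()


@pytest.fixture(scope="session")
def core_efms(core_model):
    """Full enumeration of the packaged core network (shared; ~5-10 s)."""
    return enumerate_efms(core_model)
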