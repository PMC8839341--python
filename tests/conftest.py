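import pytest

from oligomig.chem import default_library
from oligomig.enumeration import enumerate_oligomers


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def pa_npg_library(library):
    return library.subset(["PA", "NPG"])


@pytest.fixture(scope="session")
def default_oligomers(library):
    """Full candidate database at the screening defaults (<=8 units, <=1000 Da).

    Session-scoped: the enumeration over the 17-monomer default library takes
    a few seconds and several tests share it.
    """
    return enumerate_oligomers(library)
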