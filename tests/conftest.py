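import pytest

from gagms.chem import GlycanSequence
from gagms.simulate import biomarker_trio


@pytest.fixture(scope="session")
def trio():
    """The three proposed biomarker structures (610, 652, 813)."""
    return biomarker_trio()


@pytest.fixture(scope="session")
def bm652():
    return GlycanSequence.parse("HexA-HexNAc(6S)-HexA")


@pytest.fixture(scope="session")
def bm652_uronate_isomer():
    """The rival placement: sulfate on the reducing-end uronate."""
    return GlycanSequence.parse("HexA-HexNAc-HexA(2S)")
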