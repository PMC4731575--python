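import pytest

from h1ptm.chem_core import registry_default
from h1ptm.digestion import ProteinRecord


@pytest.fixture(scope="session")
def registry():
    return registry_default()


@pytest.fixture()
def toy_protein():
    """A small protein with mature chain starting at Met-inclusive position 2."""
    return ProteinRecord(
        id="TOY1",
        sequence="SAAKAARAAKPAATPAKAA",  # mature (Met removed)
        met_removed=True,
        domain_annotations=(("NTD", 2, 8), ("GH1", 9, 14), ("CTD", 15, 20)),
    )
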