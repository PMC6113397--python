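import pytest

from halosyn import thermo


@pytest.fixture(scope="session")
def species_table():
    return thermo.load_species()


@pytest.fixture(scope="session")
def reactions(species_table):
    return thermo.load_reactions(table=species_table)
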