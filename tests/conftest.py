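import pytest
from hypothesis import settings

from sloegen.core_io import load_fixture, sgenotypes_as_locus

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table1():
    """(accessions, sgenotypes) of the published 17-accession panel."""
    return load_fixture("table1_sgenotypes")


@pytest.fixture(scope="session")
def table1_sgenotypes(table1):
    return table1[1]


@pytest.fixture(scope="session")
def table1_accessions(table1):
    return table1[0]


@pytest.fixture(scope="session")
def sgen_by_id(table1_sgenotypes):
    return {sg.accession_id: sg for sg in table1_sgenotypes}


@pytest.fixture(scope="session")
def s_as_locus(table1_sgenotypes):
    """The panel's S-genotypes viewed as a single multiallelic pseudo-locus."""
    return sgenotypes_as_locus(table1_sgenotypes)


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_locus_stats")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_salleles")
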