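import pytest

from pgxforge import fixtures


@pytest.fixture(scope="session")
def clinical_panel():
    return fixtures.clinical_panel()


@pytest.fixture(scope="session")
def full_panel():
    return fixtures.full_panel()


@pytest.fixture(scope="session")
def clinical_tables(clinical_panel):
    return fixtures.allele_tables(clinical_panel)


@pytest.fixture(scope="session")
def full_tables(full_panel):
    return fixtures.allele_tables(full_panel)


@pytest.fixture(scope="session")
def maps():
    return fixtures.phenotype_maps()


@pytest.fixture(scope="session")
def rec_table(maps):
    return fixtures.recommendation_table(maps)
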