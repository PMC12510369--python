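import pytest

from ghmine import synthetic_data as sd


@pytest.fixture(scope="session")
def secretome_table():
    """The packaged 17-protein secretome worked example."""
    return sd.secretome_fixture()


@pytest.fixture(scope="session")
def small_metagenome():
    """A small enrichment-scenario metagenome with ground truth."""
    community = sd.enrichment_community(n_orfs=150, seed=11)
    return sd.generate_metagenome(community)
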