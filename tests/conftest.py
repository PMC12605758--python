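import pytest

from asrkit.examples import toy_gene_gff3_path
from asrkit.synthetic_data import SpeciesSimParams, simulate_species_table


@pytest.fixture(scope="session")
def toy_gff():
    """Packaged 33-bp toy gene: isoforms 16/9/19 bp over a 25-bp footprint."""
    return toy_gene_gff3_path()


@pytest.fixture(scope="session")
def species_panel():
    """Default 670-species panel with the quartic support-ASR structure."""
    return simulate_species_table(SpeciesSimParams(seed=1))
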