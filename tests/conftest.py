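import pytest

from mitocomp import reference
from mitocomp.synthetic_data import SimulationConfig, generate_root_genome, simulate


@pytest.fixture(scope="session")
def ref_tables():
    """The three bundled reference gene tables keyed by species code."""
    return {sp: reference.gene_table(sp) for sp in reference.SPECIES}


@pytest.fixture(scope="session")
def ref_df():
    return reference.load_dataframe()


@pytest.fixture(scope="session")
def root_genome():
    """One deterministic synthetic root mitogenome plus its ledger."""
    return generate_root_genome(SimulationConfig(seed=17))


@pytest.fixture(scope="session")
def quartet():
    """Synthetic congeners + outgroup evolved on ((ST,SA),SM,OUT)."""
    leaves, ledger = simulate(SimulationConfig(seed=23))
    return leaves, ledger
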