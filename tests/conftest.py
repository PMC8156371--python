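import dendropy
import pytest

from spatdiv.datamodel import OccurrenceMatrix, Phylogeny
from spatdiv.synth import ScenarioConfig, simulate_dataset


@pytest.fixture
def toy_occ():
    """Three taxa on two cells: A endemic to c1, C to c2, B shared."""
    return OccurrenceMatrix.from_records(
        [("A", "c1"), ("B", "c1"), ("B", "c2"), ("C", "c2")]
    )


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return Phylogeny(
        dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A complete small synthetic dataset shared across tests."""
    config = ScenarioConfig(
        seed=2021, n_taxa=80, grid_rows=10, grid_cols=10,
        logseries_p=0.95, trait_coverage=0.9, cohesion=0.6,
    )
    return simulate_dataset(config)
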