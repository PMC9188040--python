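import pytest
from hypothesis import HealthCheck, settings

from peptaxa import (
    FragmentationParams,
    SimulationSpec,
    Taxon,
    TaxonomyTree,
    build_index,
    simulate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_tree() -> TaxonomyTree:
    """Hand-built taxonomy: two genera under one domain.

    root(1) -> Bacteria(2) -> GenusA(10) -> speciesA1(100), speciesA2(101)
                           -> GenusB(11) -> speciesB1(110)
    """
    return TaxonomyTree(
        [
            Taxon(1, "root", "no rank", 1),
            Taxon(2, "Bacteria", "superkingdom", 1),
            Taxon(10, "GenusA", "genus", 2),
            Taxon(11, "GenusB", "genus", 2),
            Taxon(100, "speciesA1", "species", 10),
            Taxon(101, "speciesA2", "species", 10),
            Taxon(110, "speciesB1", "species", 11),
        ]
    )


@pytest.fixture(scope="session")
def noiseless_data():
    """Seeded noiseless synthetic community (default scale, 500 reads)."""
    return simulate(SimulationSpec(substitution_rate=0.0, seed=7))


@pytest.fixture(scope="session")
def kmer_index(noiseless_data):
    """9-mer index over the synthetic reference proteome."""
    return build_index(
        noiseless_data.proteins,
        FragmentationParams(mode="kmer", k=9),
        noiseless_data.tree,
    )
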