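import pytest

from hapchar import synthetic as syn


@pytest.fixture(scope="session")
def dup_genome():
    """400 kb genome with 5 planted duplications and 20 genes (5 duplicated)."""
    genome, truth = syn.generate_genome(seed=11, scaffolds=[400_000])
    genome, truth = syn.plant_duplications(
        genome, n_events=5, length_range=(4_000, 9_000),
        identity_range=(0.95, 1.0), tandem_fraction=0.5, seed=12, truth=truth,
    )
    genome, truth = syn.plant_genes(
        genome, n_genes=20, dup_overlap_fraction=0.25, seed=13, truth=truth,
    )
    return genome, truth


@pytest.fixture(scope="session")
def small_genome():
    genome, truth = syn.generate_genome(seed=1, scaffolds=[50_000])
    return genome, truth
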