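import pytest

from duovar import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    return sd.GenomeSpec(names=("chr1", "chr2"), lengths=(150_000, 120_000))


@pytest.fixture(scope="session")
def gene_set(small_genome):
    return sd.simulate_gene_models(small_genome, n_genes=10, seed=42)
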