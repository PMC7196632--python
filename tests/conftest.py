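import pytest

from nadhub import simulate as sim


@pytest.fixture(scope="session")
def protein_families():
    """Three planted protein families with truth labels."""
    seqs, truth = sim.gen_protein_families(k=3, n_per_family=6, seed=11)
    return seqs, truth.params["labels"]


@pytest.fixture(scope="session")
def genome_set():
    """Mixed genome scenario exercising every island-pipeline discard rule."""
    return sim.gen_genome_set(n_genomes=30, p_pair=0.6, seed=7)
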