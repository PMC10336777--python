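"""Shared fixtures: small simulated genome sets reused across test modules."""

import pytest

from polyhomeo3 import sim


@pytest.fixture(scope="session")
def small_genomes():
    """3 subgenomes x 10 genes at the default divergence regime."""
    return sim.simulate_subgenomes(sim.SimConfig(n_genes=10, seed=11))


@pytest.fixture(scope="session")
def small_reads(small_genomes):
    """2000 3'-anchored reads with truth labels from the small genome set."""
    return sim.simulate_3prime_reads(
        small_genomes, sim.ReadSimConfig(n_reads=2000, seed=12)
    )


@pytest.fixture(scope="session")
def small_index(small_genomes):
    from polyhomeo3 import aligner

    return aligner.build_index(small_genomes.references)
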