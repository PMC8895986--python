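"""Shared fixtures: small genomes and founder populations for fast tests."""

import numpy as np
import pytest

import kelpsim as ks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    return ks.GenomeParams(
        n_chromosomes=6, sites_per_chromosome=80, qtl_per_chromosome=16
    )


@pytest.fixture(scope="session")
def small_founders(small_genome):
    """A compact founder population reused across read-only tests."""
    return ks.simulate_founders(
        ks.FounderConfig(
            effective_population_size=30, n_founders=200, burn_in_generations=25
        ),
        small_genome,
        np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def small_trait(small_founders):
    return ks.TraitModel.from_founders(
        small_founders.haplotypes,
        small_founders.qtl_sites,
        heritability=0.5,
        rng=np.random.default_rng(8),
    )
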