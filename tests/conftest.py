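"""Shared fixtures: one default simulation reused across the suite."""

import pytest

from ssr_popscan.simulate import (SimConfig, simulate_conservation, simulate_genome,
                                  simulate_genotypes)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def sim_genotypes(sim_config, sim_genome):
    return simulate_genotypes(sim_config, sim_genome.truth_loci)


@pytest.fixture(scope="session")
def sim_conservation(sim_config, sim_genome):
    return simulate_conservation(sim_config, sim_genome.truth_loci,
                                 sim_genome.chrom_lengths)


@pytest.fixture(scope="session")
def n_samples(sim_config):
    return sum(ns for _g, ns, _h in sim_config.pop.breeds.values())
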