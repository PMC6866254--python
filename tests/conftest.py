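import pytest

from salmonigh import datasets
from salmonigh.simdata import (
    SimConfig,
    directory_from_loci,
    simulate_germline_locus,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def salmon_table():
    return datasets.salmon_v_gene_table()


@pytest.fixture(scope="session")
def trout_table():
    return datasets.trout_v_gene_table()


@pytest.fixture(scope="session")
def trout_locations():
    return datasets.trout_v_location_table()


@pytest.fixture(scope="session")
def sim_locus():
    """Default single-locus simulation used across tests (seed fixed)."""
    cfg = SimConfig(seed=7)
    loci, table, truth = simulate_germline_locus(cfg)
    return cfg, loci, table, truth


@pytest.fixture(scope="session")
def sim_directories(sim_locus):
    _, loci, _, _ = sim_locus
    return {g: directory_from_loci(loci, group=g) for g in ("V", "D", "J")}


@pytest.fixture(scope="session")
def sim_repertoire(sim_locus, sim_directories):
    cfg, _, _, _ = sim_locus
    cfg2 = SimConfig(seed=cfg.seed, n_reads=80)
    reads, truth = simulate_repertoire(sim_directories, cfg2)
    return reads, truth
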