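"""Shared fixtures: small synthetic panels reused across test modules."""

import numpy as np
import pytest

from mgwaskit import genostruct, sim


@pytest.fixture(scope="session")
def small_panel():
    """72 parents, 150 hybrids, 2 chromosomes x 15 blocks."""
    cfg = sim.SimConfig(n_hybrids=150, n_chromosomes=2, n_blocks_per_chr=15,
                        n_features=10, seed=11)
    panel = sim.simulate_parents(cfg)
    geno = sim.make_hybrids(panel, config=cfg)
    return cfg, panel, geno


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    _, _, geno = small_panel
    return genostruct.compute_ais_kinship(geno)


@pytest.fixture(scope="session")
def small_designs(small_panel):
    _, _, geno = small_panel
    sets = genostruct.build_coinherited_sets(geno)
    refs = genostruct.filter_reference_snps(geno, sets)
    return sets, refs, genostruct.encode_designs(geno, snps=refs)


@pytest.fixture(scope="session")
def calibration_panel():
    """Mid-size panel for the statistical-engine tests: 200 hybrids,
    5 chromosomes x 40 blocks (~200 reference SNPs)."""
    cfg = sim.SimConfig(n_hybrids=200, n_chromosomes=5, n_blocks_per_chr=40,
                        snps_per_block=(1, 8), n_features=1, seed=17)
    panel = sim.simulate_parents(cfg)
    geno = sim.make_hybrids(panel, config=cfg)
    kin = genostruct.compute_ais_kinship(geno)
    sets = genostruct.build_coinherited_sets(geno)
    refs = genostruct.filter_reference_snps(geno, sets)
    designs = genostruct.encode_designs(geno, snps=refs)
    return geno, kin, sets, designs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
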