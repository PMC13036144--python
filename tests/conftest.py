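import numpy as np
import pytest

from tobgs import simdata


@pytest.fixture(scope="session")
def small_panel():
    """200 individuals, 4 chromosomes x 150 markers — shared read-only."""
    geno, gmap = simdata.simulate_genotypes(
        simdata.SimConfig(
            n_individuals=200, n_chromosomes=4, n_markers_per_chrom=150, seed=3
        )
    )
    return geno, gmap


@pytest.fixture(scope="session")
def small_trait(small_panel):
    geno, _ = small_panel
    pheno, truth = simdata.simulate_trait(
        geno, simdata.TraitConfig(h2_target=0.7, n_qtl=100, seed=3)
    )
    return pheno, truth


@pytest.fixture(scope="session")
def tiny_panel():
    """120 individuals, 2 chromosomes x 60 markers — for brute-force oracles."""
    geno, gmap = simdata.simulate_genotypes(
        simdata.SimConfig(
            n_individuals=120, n_chromosomes=2, n_markers_per_chrom=60, seed=9
        )
    )
    return geno, gmap
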