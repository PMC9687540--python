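import numpy as np
import pytest

from genegwas import (GeneCatalog, GenotypePanel, SimConfig,
                      simulate_genotype_panel)


@pytest.fixture
def tiny_panel():
    """4 inbred samples x 5 SNPs on two chromosomes, one missing entry."""
    dosage = np.array([
        [0, 2, 0, 0, 2],
        [2, 0, 2, 0, 2],
        [0, 2, 2, 2, np.nan],
        [2, 0, 0, 0, 2],
    ], dtype=float)
    return GenotypePanel(
        sample_ids=[f"s{i}" for i in range(4)],
        snp_ids=[f"snp{j}" for j in range(5)],
        chrom=["1", "1", "1", "2", "2"],
        pos=[100, 200, 300, 150, 250],
        dosage=dosage,
    )


@pytest.fixture
def tiny_catalog():
    return GeneCatalog(
        gene_id=["g1", "g2"],
        chrom=["1", "2"],
        start=[50, 100],
        end=[250, 300],
        strand=["+", "-"],
    )


@pytest.fixture(scope="session")
def sim_panel():
    """Moderate simulated panel shared across tests (deterministic)."""
    cfg = SimConfig(n_individuals=150, n_genes=60, seed=7)
    return simulate_genotype_panel(cfg)
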