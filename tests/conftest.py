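import numpy as np
import pytest

from polysub import simulate as sim


@pytest.fixture(scope="session")
def divergence_genome():
    """1,000 homoeolog pairs of 300 codons under the default divergence
    scenario (5 Myr at 1.5e-8 per synonymous site per year), no gene loss."""
    cfg = sim.SimConfig(seed=101, n_chromosome_pairs=2, genes_per_chromosome=500,
                        codons_per_gene=300, fractionation_rate_A=0.0,
                        fractionation_rate_B=0.0, tandem_rate=0.0,
                        inversion_count=0, intergenic_length=10)
    return cfg, sim.simulate_progenitors(cfg)


@pytest.fixture(scope="session")
def ltr_landscape():
    """Default TE landscape (6 subgenome-specific + 4 shared families) on a
    minimal host genome."""
    cfg = sim.SimConfig(seed=202, n_chromosome_pairs=2, genes_per_chromosome=3,
                        codons_per_gene=100, intergenic_length=10,
                        inversion_count=0)
    genome = sim.simulate_progenitors(cfg)
    sim.simulate_ltr_landscape(cfg, genome)
    return cfg, genome


@pytest.fixture(scope="session")
def atlas_genome():
    """2,000-pair, 10-tissue, 3-replicate atlas with the packaged bias
    configuration and identical homoeolog sequences (expression only)."""
    cfg = sim.SimConfig(seed=303, n_chromosome_pairs=2, genes_per_chromosome=1000,
                        codons_per_gene=100, t_divergence=0.0, t_merger=0.0,
                        fractionation_rate_A=0.0, fractionation_rate_B=0.0,
                        tandem_rate=0.0, inversion_count=0, intergenic_length=10)
    genome = sim.simulate_progenitors(cfg)
    sim.simulate_atlas(cfg, genome)
    return cfg, genome


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
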