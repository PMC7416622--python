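import numpy as np
import pytest

from wgdkit.simulate import SimConfig, WgdSpec, simulate_dataset


@pytest.fixture(scope="session")
def single_wgd_result():
    """One species, one WGD at pairwise Ks 1.0 with 30% retention."""
    cfg = SimConfig(
        species_newick="(A:0.75);",
        wgd_events=[WgdSpec(branch="A", age_ks=1.0, retention_prob=0.3)],
        n_families=200,
        genes_per_scaffold=50,
        cds_codons=300,
        fractionation_prob=0.0,
        n_inversions=0,
        small_scale_dup_rate=0.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def stem_wgd_result():
    """Three ingroup species + outgroup; WGD on the ingroup stem branch."""
    cfg = SimConfig(
        species_newick="((A:0.35,(B:0.2,C:0.2):0.15):0.55,O:0.9);",
        wgd_events=[WgdSpec(branch=("A", "B", "C"), age_ks=1.0, retention_prob=0.3)],
        n_families=80,
        genes_per_scaffold=40,
        cds_codons=300,
        fractionation_prob=0.0,
        n_inversions=0,
        small_scale_dup_rate=0.0,
        seed=17,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
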