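import numpy as np
import pytest

from slsplice.discovery import SpliceLeader
from slsplice.simulate import DEFAULT_LEADERS, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def leaders():
    return list(DEFAULT_LEADERS)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free single-genotype dataset for discovery tests."""
    cfg = SimConfig(
        n_genes=10,
        seed=101,
        genotypes=("wt",),
        psi_by_genotype=(0.75,),
        n_replicates=1,
        reads_per_gene=30,
        substitution_error_rate=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def diff_sim():
    """Two-genotype dataset with planted RO/CSRO/ALT3TSS/null events."""
    cfg = SimConfig(
        n_genes=12,
        seed=202,
        n_replicates=3,
        reads_per_gene=50,
        frac_csro=0.25,
        frac_alt3tss=0.25,
        frac_null=0.25,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
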