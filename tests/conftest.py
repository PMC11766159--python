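import numpy as np
import pytest

from ecckit.config import SimConfig
from ecckit import simulate as sim


@pytest.fixture(scope="session")
def base_config():
    """Small but fully featured simulation used by several test modules."""
    return SimConfig(
        seed=11,
        chrom_lengths=[200_000, 150_000, 120_000],
        n_ecc_loci=150,
        n_genes=45,
        genic_fraction_target=0.5,
        planted_motif_fraction=0.3,
        de_fraction=0.2,
        cond_specific_fraction=0.2,
        circ_shared_fraction=0.3,
        n_circ_total=50,
        n_mirna_precursors=30,
        mirna_inside_fraction=0.5,
        expr_coupling_rho=0.5,
    )


@pytest.fixture(scope="session")
def dataset(base_config):
    return sim.simulate_dataset(base_config)


@pytest.fixture(scope="session")
def dataset_dir(dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("dataset")
    sim.write_dataset(dataset, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
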