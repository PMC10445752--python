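import numpy as np
import pytest

from itb_regnet.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted bundle shared by read-only tests."""
    cfg = SimConfig(
        n_peaks=400,
        n_celltypes=3,
        n_nuclei_per_type=60,
        n_specific_per_type=20,
        n_genes=120,
        n_decoy_motifs=8,
        junk_fraction=0.05,
        seed=101,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's standing study conditions (planted effects, seed 0)."""
    return generate_dataset(SimConfig(junk_fraction=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
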