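import warnings

import numpy as np
import pytest

from gliotex import lbp3d, synthetic_cohort as sc

# sklearn warns when a class has fewer members than n_splits on tiny cohorts;
# irrelevant to what the tests assert
warnings.filterwarnings("ignore", message="The least populated class")


@pytest.fixture(scope="session")
def sampling32():
    return lbp3d.build_sampling(32, 3)


@pytest.fixture(scope="session")
def small_config():
    return lbp3d.LbpConfig(radii_mm=(1.0, 2.0, 3.0), n_dirs=16, max_degree=3)


@pytest.fixture(scope="session")
def tiny_spec():
    """A 12-patient cohort on a 32^3 grid, small tumors, both genotypes present."""
    return sc.CohortSpec(
        n_patients=12, mutant_prob=0.6, grid_shape=(32, 32, 32),
        mutant_size_mean=6.0, wild_size_mean=4.5, size_sd=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return sc.sample_cohort(tiny_spec)


@pytest.fixture(scope="session")
def textured_volume():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(11)
    vol = gaussian_filter(rng.standard_normal((40, 40, 40)), 2.0)
    return vol / vol.std()
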