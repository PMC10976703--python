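import numpy as np
import pytest

import petvoi as pv

PRINTED_SIZES = {"CN": 40, "MCI_NC": 38, "MCI_C": 44, "AD": 42}


@pytest.fixture(scope="session")
def small_atlas():
    """Compact block atlas used across imaging tests (3 mm isotropic)."""
    return pv.generate_atlas_phantom((32, 32, 32), (3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def printed_cohort():
    """Cohort at the published group sizes, seed 0, with intervals filled."""
    cohort = pv.generate_cohort(PRINTED_SIZES, seed=0)
    return pv.assign_conversion_times(cohort, seed=0)


@pytest.fixture(scope="session")
def uniform_volume(small_atlas):
    """Flat activity field over the whole grid."""
    data = np.full(small_atlas.shape, 500.0)
    return pv.PetVolume(data, small_atlas.voxel_size_mm, small_atlas.affine.copy())
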