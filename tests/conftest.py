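import numpy as np
import pytest

from plsmem.design import (DesignParams, SdtParams, generate_design,
                           generate_word_pool, simulate_cohort)
from plsmem.grid import VoxelGrid
from plsmem.imagesim import default_planted_model, simulate_condition_images
from plsmem.design import MODELED_CONDITIONS


@pytest.fixture(scope="session")
def default_params():
    return DesignParams(rng_seed=7)


@pytest.fixture(scope="session")
def default_design(default_params):
    pool = generate_word_pool(default_params)
    return generate_design(pool, default_params, counterbalance_id=0)


@pytest.fixture(scope="session")
def cohort_responses(default_params):
    """14-subject cohort at the calibrated response probabilities."""
    return simulate_cohort(default_params, SdtParams(mode="rate"),
                           rng_seed=7)


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid(shape=(6, 6, 5), affine=np.array([
        [2.0, 0, 0, -5.0], [0, 2.0, 0, -5.0],
        [0, 0, 2.0, -4.0], [0, 0, 0, 1.0]]))


@pytest.fixture(scope="session")
def planted_images():
    """Default study-like image set: 14 subjects, 6 conditions."""
    grid, model = default_planted_model()
    return simulate_condition_images(14, MODELED_CONDITIONS, grid, model,
                                     rng_seed=11)
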