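"""Shared fixtures: input functions, a small phantom, simulated datasets.

Everything is generated programmatically; the phantom used by most tests is
a reduced 12x12x10 grid so that voxelwise fits stay fast, while acceptance
tests build the full default phantom themselves.
"""

import numpy as np
import pytest

from petki import (FengParams, build_phantom, make_dataset, population_if,
                   uniform_grid)

SMALL_SHAPE = (12, 12, 10)
SMALL_LESION = {"center": (6.0, 2.0, 2.0)}


@pytest.fixture(scope="session")
def feng_cp():
    """Default population bolus sampled on a 1-s grid with delay headroom."""
    return population_if(FengParams(), uniform_grid(3660.0))


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom({"shape": SMALL_SHAPE, "lesions": [SMALL_LESION]})


@pytest.fixture(scope="session")
def p1_dataset(small_phantom):
    return make_dataset("P1", phantom=small_phantom)


@pytest.fixture(scope="session")
def p2_dataset(small_phantom):
    return make_dataset("P2", phantom=small_phantom)


@pytest.fixture(scope="session")
def p3_dataset(small_phantom):
    return make_dataset("P3", phantom=small_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
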