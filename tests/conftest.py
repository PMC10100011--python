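import numpy as np
import pytest
from dataclasses import replace

from carotiq.imagevol import VoxelGrid
from carotiq.phantom import PhantomSpec, generate_phantom

SMALL_GRID = VoxelGrid(shape=(30, 64, 64), spacing_mm=(3.0, 1.37, 1.37))


@pytest.fixture(scope="session")
def noisefree_spec():
    """Default phantom conditions with all noise and blur-independent terms
    switched off where tests need exact tissue values."""
    return replace(PhantomSpec(), noise_sd_suv=0.0, ct_noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def noisefree_case(noisefree_spec):
    return generate_phantom(noisefree_spec)


@pytest.fixture(scope="session")
def small_noisefree_case():
    spec = replace(PhantomSpec(), grid=SMALL_GRID, noise_sd_suv=0.0,
                   ct_noise_sd_hu=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_case():
    return generate_phantom(PhantomSpec(seed=11))
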