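import numpy as np
import pytest

from mwcam.geometry import CameraGeometry
from mwcam.phantoms import GridSpec, PhantomConfig, TissueDielectrics
from mwcam.pipeline import simulate_sample
from mwcam.spectral import SpectralGrid, crop_box, visible_filter


@pytest.fixture(scope="session")
def geometry():
    return CameraGeometry()


@pytest.fixture(scope="session")
def sgrid(geometry):
    return SpectralGrid(geometry)


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def nominal():
    return TissueDielectrics()


@pytest.fixture(scope="session")
def mask17(sgrid, geometry):
    ones = np.ones((geometry.n_retina, geometry.n_retina), dtype=complex)
    return crop_box(visible_filter(ones, sgrid, fraction=0.5)).mask


@pytest.fixture(scope="session")
def small_samples(geometry, grid):
    """A handful of simulated samples for scaling/network tests."""
    configs = [
        PhantomConfig(1, 1, tumor_case=1, jitter_seed=100),
        PhantomConfig(1, 2, tumor_case=2, jitter_seed=101),
        PhantomConfig(2, 3, tumor_case=3, rotation=4, jitter_seed=102),
        PhantomConfig(2, 4, tumor_case=4, mirror=True, jitter_seed=103),
        PhantomConfig(3, 5, tumor_case=4, rotation=9, jitter_seed=104),
        PhantomConfig(3, 1, tumor_case=1, mirror=True, rotation=2, jitter_seed=105),
    ]
    return [simulate_sample(c, geometry, grid, split="train") for c in configs]
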