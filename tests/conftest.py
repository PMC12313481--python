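import numpy as np
import pytest

from kinhet import PhantomSpec, segment_tumor, simulate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A ~11k-voxel noiseless phantom with mixed kinetic classes."""
    spec = PhantomSpec(seed=7, class_proportions=(0.3, 0.3, 0.4), noise_sd=0.0)
    return spec, simulate_phantom(spec)


@pytest.fixture(scope="session")
def segmented_phantom(noiseless_phantom):
    spec, result = noiseless_phantom
    sub = segment_tumor(result.series, result.tumor_mask)
    return result, sub


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
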