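import numpy as np
import pytest

from svperf.phantom import PhantomConfig, simulate_study


def small_config(**overrides) -> PhantomConfig:
    """A 40-voxel-cube phantom that runs in a fraction of a second."""
    base = dict(
        grid_shape=(40, 40, 40),
        myo_geometry=dict(center_mm=(10.0, 9.0, 9.0),
                          outer_radii_mm=(8.0, 7.0, 7.0),
                          inner_radii_mm=(5.0, 4.0, 4.0)),
        aorta_geometry=dict(center_yx_mm=(16.0, 16.0), radius_mm=1.8),
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def default_study():
    """Noiseless default phantom (64-cube, uniform 0.92 mL/min/g truth)."""
    return simulate_study(PhantomConfig())


@pytest.fixture(scope="session")
def small_study():
    """Noiseless small phantom for fast unit tests."""
    return simulate_study(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20241)
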