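import pytest

from metapva import Landscape, Patch, generate_synthetic_landscape, load_config


@pytest.fixture(scope="session")
def preset():
    """Default synthetic 36-patch, 3-cluster landscape."""
    return generate_synthetic_landscape(seed=0)


@pytest.fixture()
def defaults():
    """(ModelParams, SimConfig) at the documented defaults."""
    return load_config()


@pytest.fixture()
def two_patch():
    """Two identical mid-sized patches 100 m apart (K = 100 at K_volume = 17)."""
    k_target = 100.0
    depth = 2.0
    area = k_target / (17.0 * depth)
    return Landscape(
        [
            Patch(1, area, depth, 0.0, 0.0),
            Patch(2, area, depth, 100.0, 0.0),
        ]
    )
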