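import math

import pytest

from corowave.synthetic_data import SyntheticConfig, generate_tree
from corowave.tree_model import VascularTree, VesselSegment


@pytest.fixture
def minimal_tree() -> VascularTree:
    """Root with two daughters: areas 2.5, 2.0, 1.0 mm^2 -> sigma=1.2, gamma=0.5."""
    r = lambda area: math.sqrt(area / math.pi)
    return VascularTree(
        [
            VesselSegment("m", None, r(2.5), 10.0),
            VesselSegment("a", "m", r(2.0), 8.0),
            VesselSegment("b", "m", r(1.0), 6.0),
        ]
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        root_radius=1.5, r_min=0.08, max_segments=500, seed=3
    )


@pytest.fixture(scope="session")
def small_tree(small_config) -> VascularTree:
    return generate_tree(small_config)


@pytest.fixture(scope="session")
def default_tree() -> VascularTree:
    return generate_tree(SyntheticConfig(seed=0))
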