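import numpy as np
import pytest

import residuecov as rc


@pytest.fixture(scope="session")
def known_params():
    """Generating parameters used for consistent-pair fixtures."""
    return rc.SegmentationParams(c_r=-2.0, c_g=1.0, c_b=3.0, threshold=120.0)


@pytest.fixture(scope="session")
def mini_spec():
    """A 64x48 scene whose straws survive the 5x5 median filter."""
    return rc.SceneSpec(height=48, width=64, seed=42,
                        straw_length_range=(10, 24), straw_width_range=(3, 5))


@pytest.fixture(scope="session")
def mini_scene(mini_spec):
    return rc.generate_scene(mini_spec)


@pytest.fixture(scope="session")
def consistent_pair(known_params, mini_spec):
    """(image, template) with a fitness-0 optimum at known_params."""
    return rc.generate_consistent_pair(known_params, spec=mini_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
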