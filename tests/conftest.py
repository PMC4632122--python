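import numpy as np
import pytest

import swirindex as sx


@pytest.fixture(scope="session")
def default_axis():
    return sx.SpectralAxis()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cube():
    """A 4x4x8 cube with random intensities and a generic wavelength axis."""
    gen = np.random.default_rng(7)
    axis = sx.SpectralAxis(900.0 + 10.0 * np.arange(8))
    return sx.HyperspectralCube(
        intensities=gen.uniform(1.0, 100.0, size=(4, 4, 8)),
        axis=axis,
        light_reference=gen.uniform(0.5, 2.0, size=8),
    )


@pytest.fixture(scope="session")
def standard_scene():
    """The standard two-leaf scene: water 1.0 vs 0.8, default noise, seed 1."""
    cube, masks = sx.two_leaf_scene(water_a=1.0, water_b=0.8, seed=1)
    return cube, masks


@pytest.fixture(scope="session")
def standard_union_mask(standard_scene):
    _, masks = standard_scene
    return masks[0] | masks[1]


@pytest.fixture(scope="session")
def standard_search(standard_scene, standard_union_mask):
    """Full-range stride-8 ratio search on the standard scene (shared: slow)."""
    cube, _ = standard_scene
    return sx.search_indices(cube, standard_union_mask, stride=8)
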