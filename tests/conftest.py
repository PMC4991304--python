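import numpy as np
import pytest

from colonypat import (
    ColonySpec,
    SceneSpec,
    build_default_library,
    build_library,
    sample_class_patches,
)


@pytest.fixture(scope="session")
def default_library():
    """A full 200-patch-per-class taught library (the standard size)."""
    return build_default_library(200, seed=1)


@pytest.fixture(scope="session")
def small_library():
    """A cheap 40-patch-per-class library for unit tests."""
    return build_default_library(40, seed=11)


@pytest.fixture(scope="session")
def tiny_library():
    """A 4x5-patch library, small enough for exhaustive oracles."""
    patches = sample_class_patches(5, seed=21, n_scenes=1)
    return build_library(patches)


@pytest.fixture(scope="session")
def held_out_patches():
    """Pure patches drawn from scenes textured independently of any library."""
    return sample_class_patches(50, seed=77)


@pytest.fixture()
def two_colony_scene():
    """A 768x768 field with two mid-sized colonies."""
    return SceneSpec(
        image_height_px=768,
        image_width_px=768,
        colonies=(
            ColonySpec(center_rc=(200.0, 210.0), initial_diameter_um=500.0),
            ColonySpec(center_rc=(540.0, 540.0), initial_diameter_um=380.0),
        ),
        growth_rate_um_per_h=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
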