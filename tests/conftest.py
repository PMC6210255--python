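import numpy as np
import pytest

from glucolens import (
    SceneSpec,
    default_optical_map,
    default_swelling_params,
    lens_optical_map,
    render_frame,
)


@pytest.fixture(scope="session")
def params():
    return default_swelling_params()


@pytest.fixture(scope="session")
def pdms_map():
    return default_optical_map()


@pytest.fixture(scope="session")
def lens_map(params):
    return lens_optical_map(params)


@pytest.fixture(scope="session")
def anchor_frame():
    """Noise-free frame at the lowest calibration anchor ratio."""
    spec = SceneSpec(red_area_fraction=0.418, noise_sigma=0.0, seed=1)
    return render_frame(spec)


def disc_count_bruteforce(height, width, center, radius):
    """Independent pixel-centre census of a disc, by explicit enumeration."""
    n = 0
    for r in range(height):
        for c in range(width):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                n += 1
    return n


@pytest.fixture(scope="session")
def small_scene():
    """Cheap 256-px scene for sequence-level tests."""
    return SceneSpec(height=256, width=256, sample_center=(128.0, 128.0),
                     sample_radius=100.0, noise_sigma=0.0, seed=0)
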