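import numpy as np
import pytest

from phenowell.plates import standard_layout
from phenowell.synth import GroundTruthPlate, random_plate, render_plate

# Reduced rendering resolution used throughout the tests: same aspect as the
# platform camera, small enough to keep the suite fast.
TEST_RESOLUTION = (800, 1000)  # (height, width)


@pytest.fixture(scope="session")
def layout12():
    return standard_layout("12-well")


@pytest.fixture(scope="session")
def layout24():
    return standard_layout("24-well")


@pytest.fixture(scope="session")
def clean_plate12(layout12):
    """A 12-well plate with known areas, identity-ish pose, no distortion or
    noise — the simplest ground-truthed input."""
    truth = GroundTruthPlate(
        layout=layout12, areas=[5000] * 12, rng_seed=42,
        image_size=TEST_RESOLUTION, transform_params=(1.0, 0.0, 0.0, 0.0),
        distortion_k=0.0, noise_sd=0.0)
    return truth, render_plate(truth)


@pytest.fixture(scope="session")
def random_plate24():
    """One randomly posed, distorted, noisy 24-well plate."""
    truth = random_plate("24-well", image_size=TEST_RESOLUTION, seed=11)
    return truth, render_plate(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
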