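import numpy as np
import pytest

from navlab.geometry import CameraIntrinsics, random_rigid_transform
from navlab.study import StudyConfig, run_study
from navlab.synthetic import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def intrinsics():
    return CameraIntrinsics(fx=800.0, fy=820.0, cx=480.0, cy=270.0, image_width=960, image_height=540)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomConfig(seed=3))


@pytest.fixture
def random_transform(rng):
    def make(from_frame="I", to_frame="P", scale=150.0):
        return random_rigid_transform(rng, from_frame, to_frame, translation_scale=scale)

    return make


@pytest.fixture(scope="session")
def default_study_report():
    """One seeded run of the default (scaled-down) study, shared across tests."""
    return run_study(StudyConfig(seed=1))
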