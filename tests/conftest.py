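import numpy as np
import pytest

from stereogaze.experiments import calibrate_subject, validation_target_grid
from stereogaze.scene import default_scene
from stereogaze.simulator import SubjectParams


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def subject():
    """Default binocular subject (temporal kappa ~5 deg, IOD 63 mm)."""
    return SubjectParams()


@pytest.fixture(scope="session")
def calibrations(scene, subject):
    """Noiseless single-point kappa calibrations for the default subject."""
    return calibrate_subject(subject, scene, noise_px=0.0, duration_s=0.4)


@pytest.fixture(scope="session")
def target_grid():
    return validation_target_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
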