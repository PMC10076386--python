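import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from torsometrics import SynthParams, generate_torso, measure_all

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: a mixed deformity pattern used by several fixtures
DEFORMED = dict(
    shoulder_tilt_deg=10.0,
    shoulder_rotation_deg=-5.0,
    scapula_prominence_left=12.0,
    scapula_prominence_right=4.0,
    scapula_height_offset=15.0,
    psis_rotation_deg=6.0,
    psis_height_offset_deg=5.0,
    rib_hump_deg=15.0,
    head_shift=20.0,
)


@pytest.fixture(scope="session")
def symmetric_torso():
    """Noiseless torso with every deformity parameter at zero."""
    return generate_torso(SynthParams())


@pytest.fixture(scope="session")
def deformed_torso():
    """Noiseless torso with all deformities switched on at once."""
    return generate_torso(SynthParams(**DEFORMED))


@pytest.fixture(scope="session")
def deformed_values(deformed_torso):
    mesh, truth = deformed_torso
    report = measure_all(mesh, truth.roi_config)
    assert not report.errors
    return report.values()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
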