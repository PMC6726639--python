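import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def leaflet_protocol():
    from mvmech.kinematics import default_leaflet_protocol

    return default_leaflet_protocol()


@pytest.fixture
def chordae_protocol():
    from mvmech.kinematics import default_chordae_protocol

    return default_chordae_protocol()


@pytest.fixture
def m1_anterior_pseudo(leaflet_protocol):
    """Noiseless pseudo-biaxial dataset from the M1 anterior parameters."""
    from mvmech import M1_ANTERIOR
    from mvmech.fitting import generate_pseudo_data

    return generate_pseudo_data(M1_ANTERIOR, leaflet_protocol)


def random_rotation(rng):
    """Uniform random 3D rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_incompressible_F(rng, max_log_stretch=0.25):
    """Random F with det F = 1: rotated diagonal stretch with R-multiplies."""
    logs = rng.uniform(-max_log_stretch, max_log_stretch, 2)
    lam = np.exp(np.array([logs[0], logs[1], -logs[0] - logs[1]]))
    R1 = random_rotation(rng)
    R2 = random_rotation(rng)
    return R1 @ np.diag(lam) @ R2
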