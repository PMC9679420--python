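import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from bspmaf.isopotential import InterpolationGrid
from bspmaf.synthetic import (
    generate_electrode_layout,
    generate_torso_mesh,
    simulate_recording,
)


@pytest.fixture(scope="session")
def mesh():
    return generate_torso_mesh()


@pytest.fixture(scope="session")
def layout(mesh):
    return generate_electrode_layout(mesh)


@pytest.fixture(scope="session")
def grid(layout):
    return InterpolationGrid.from_layout(layout, size=32)


@pytest.fixture(scope="session")
def sinus_recording(layout):
    """20 s sinus-rhythm recording with the default 48-degree axis."""
    return simulate_recording(
        layout, duration_s=20.0, seed=3, rhythm="sinus", axis_angle_deg=48.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
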