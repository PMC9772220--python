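import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mcginv.forward import compute_lead_field
from mcginv.geometry import make_ellipsoid_mesh, make_sensor_grid, remesh_perturb

SEMI_AXES = (4.0, 3.5, 5.0)


@pytest.fixture(scope="session")
def heart_mesh():
    """Small ventricular stand-in: 60-node ellipsoid surface."""
    return make_ellipsoid_mesh(SEMI_AXES, 60, seed=11, label="model1")


@pytest.fixture(scope="session")
def heart_mesh2(heart_mesh):
    """Independent 100-node remesh of the same surface."""
    return remesh_perturb(heart_mesh, 100, 0.0, seed=23, label="model2")


@pytest.fixture(scope="session")
def sensor_grid():
    return make_sensor_grid(9, 9, 3.0, center=(0.0, 0.0, 10.0))


@pytest.fixture(scope="session")
def lead_field(heart_mesh, sensor_grid):
    return compute_lead_field(heart_mesh, sensor_grid)


@pytest.fixture()
def toy_problem():
    """Reference 2x2 ridge toy: A = [[1,0],[0,2]], b = (1,2), lam = 1 -> (0.5, 0.8)."""
    return np.array([[1.0, 0.0], [0.0, 2.0]]), np.array([1.0, 2.0])


@pytest.fixture(scope="session")
def recovery_control():
    """Well-conditioned overdetermined noise-free control (same mesh both sides)."""
    from mcginv.source_sim import WaveformParams, simulate_sources

    mesh = make_ellipsoid_mesh(SEMI_AXES, 30, seed=3)
    grid = make_sensor_grid(9, 9, 3.0, center=(0.0, 0.0, 8.0))
    A = compute_lead_field(mesh, grid).design_matrix("all")
    src = simulate_sources(mesh, WaveformParams(dt=5.0))
    s_true = src.values[:, src.index_of_time(85.0)]
    return A, s_true, A @ s_true
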