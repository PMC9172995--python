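import numpy as np
import pytest

from incubehave.core import Trajectory, light_dark_box
from incubehave.synthetic_data import PhantomSpec, TrajectoryGenSpec, gen_dwi_phantom

WELL_SEPARATED = {
    # three 4-D Gaussian classes with means ~20 SD apart (unit variance)
    "caffeine": (np.array([20.0, 0.0, 0.0, 0.0]), np.eye(4)),
    "foot_shock": (np.array([0.0, 20.0, 0.0, 0.0]), np.eye(4)),
    "non_treated": (np.array([0.0, 0.0, 20.0, 0.0]), np.eye(4)),
}

INDISTINGUISHABLE = {
    "caffeine": (np.zeros(4), np.eye(4)),
    "foot_shock": (np.zeros(4), np.eye(4)),
    "non_treated": (np.zeros(4), np.eye(4)),
}


@pytest.fixture
def arena():
    return light_dark_box()


@pytest.fixture
def short_spec(arena):
    return TrajectoryGenSpec(
        arena=arena, n_subjects_per_group=3, duration=20.0, seed=42
    )


@pytest.fixture
def straight_trajectory(arena):
    """Constant-velocity motion along the stressor axis at 30 mm/s."""
    n = 50
    x = -50.0 + 2.0 * np.arange(n)  # 2 mm per frame at 15 Hz = 30 mm/s
    y = np.full(n, 100.0)
    return Trajectory("s0", "A", 15.0, np.column_stack([x, y]), arena=arena)


@pytest.fixture
def anisotropic_phantom():
    spec = PhantomSpec(
        grid_shape=(4, 4, 4), tensor_field=np.diag([1.5e-3, 4e-4, 3e-4])
    )
    return spec, gen_dwi_phantom(spec)
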