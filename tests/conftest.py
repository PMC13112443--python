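import numpy as np
import pytest

from membranegp.synth import ImageSpec, TrajectorySpec, make_cell_image, make_trajectory


@pytest.fixture(scope="session")
def small_image():
    """A 10-cell noisy image with ground truth, shared across tests."""
    spec = ImageSpec(image_shape=(256, 256), n_cells=10, seed=11)
    image, truth = make_cell_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def short_trajectory():
    """A 20 ns default-parameter trajectory with ground truth."""
    spec = TrajectorySpec(duration=20.0, seed=5)
    traj, truth = make_trajectory(spec)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
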