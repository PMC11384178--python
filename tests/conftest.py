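import numpy as np
import pytest

import fhpose as f


@pytest.fixture(scope="session")
def graph():
    return f.build_upper_body_graph()


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate-noise dataset at reduced size for fast training tests."""
    return f.generate_dataset(f.GeneratorConfig(n_samples=200, seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return f.generate_dataset(
        f.GeneratorConfig(n_samples=120, seed=7, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pose17(rng, scale=0.5):
    """A generic valid 17-joint pose with a non-degenerate hip axis."""
    pose = rng.normal(0.0, scale, size=(17, 3))
    pose[4] = pose[0] + np.array([0.05, 0.12, 0.0])  # keep left hip off-axis
    return pose
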