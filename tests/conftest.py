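import matplotlib
import numpy as np
import pytest

from radonflow import SpaceTimeImage, SyntheticSpec, generate_streak_image

matplotlib.use("Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_image():
    return SpaceTimeImage(np.full((40, 40), 7.0), dx=0.5, dt=1.0)


@pytest.fixture
def stripes_45():
    """Clean 45-degree streak image, no noise."""
    return generate_streak_image(SyntheticSpec(theta_true=45.0, width=100, height=100))


def make_stripes(theta, width=64, height=64, noise_sd=0.0, seed=0, **kw):
    spec = SyntheticSpec(
        theta_true=theta, width=width, height=height, noise_sd=noise_sd, seed=seed, **kw
    )
    return generate_streak_image(spec)


@pytest.fixture
def stripe_factory():
    return make_stripes
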