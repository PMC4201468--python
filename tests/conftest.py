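import numpy as np
import pytest

from directorfield import AmoebaSpec, KernelParams, SceneConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_kernel():
    """A small kernel cheap enough for brute-force comparisons."""
    return KernelParams(sigma=2.0, R_min=1.5, n_angle_bins=16)


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def amoeba_spec():
    return AmoebaSpec()


def random_field(rng, L=16, density=0.15):
    """Sparse random director field used by several oracles."""
    from directorfield import DirectorField

    mask = rng.random((L, L)) < density
    mag = np.where(mask, rng.uniform(0.2, 1.5, (L, L)), 0.0)
    theta = rng.uniform(0, np.pi, (L, L))
    return DirectorField(mag * np.exp(2j * np.where(mask, theta, 0.0)))
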