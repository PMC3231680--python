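import numpy as np
import pytest

from rededge import SceneParams, simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 10x20 scene with 20 fields: fast, noisy, field-structured."""
    return simulate_scene(SceneParams(n_rows=10, n_cols=20, n_fields=20, seed=1))


@pytest.fixture(scope="session")
def noiseless_scene():
    return simulate_scene(
        SceneParams(n_rows=10, n_cols=20, n_fields=20, seed=1, noise_sd_additive=0.0)
    )


@pytest.fixture
def fine_axis():
    return np.arange(400.0, 1001.0, 1.0)
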