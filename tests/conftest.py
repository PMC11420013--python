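import numpy as np
import pytest

from flowalign import LabelMask, SyntheticSpec, generate_monolayer


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_monolayer():
    """One small aligned synthetic monolayer shared across tests."""
    spec = SyntheticSpec(
        image_size=(160, 160), n_cells=36, stretch=3.0, kappa=8.0, rng_seed=7
    )
    return generate_monolayer(spec)


@pytest.fixture
def rectangle_mask():
    """Solid 5-column x 3-row rectangle (label 1) away from the border."""
    arr = np.zeros((12, 12), dtype=np.int32)
    arr[4:7, 3:8] = 1
    return LabelMask(pixels=arr, image_id="rect")
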