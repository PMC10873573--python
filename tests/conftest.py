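import numpy as np
import pytest

import bingo_unmix as bu


@pytest.fixture(scope="session")
def noiseless_three_color():
    """Noiseless, shift-free 3-fluorophore strip acquisition (seed 0)."""
    config = bu.default_config(3, rng_seed=0, noise_sigma=0.0, shift_nm=0.0)
    phantom = bu.strip_phantom(3, 60, 60)
    stack, mixing = bu.make_dataset(config, phantom)
    return config, phantom, stack, mixing


@pytest.fixture(scope="session")
def noiseless_three_color_result(noiseless_three_color):
    """Default-settings blind unmixing of the noiseless 3-color dataset."""
    _, phantom, stack, mixing = noiseless_three_color
    result = bu.bingo_unmix(stack, 3)
    report = bu.evaluate(result, phantom, mixing)
    return result, report


@pytest.fixture(scope="session")
def noisy_three_color():
    """3-fluorophore strips with moderate noise and per-fluorophore shift."""
    config = bu.default_config(3, rng_seed=1)
    phantom = bu.strip_phantom(3, 60, 60)
    stack, mixing = bu.make_dataset(config, phantom)
    return config, phantom, stack, mixing


def random_stack(seed: int, n: int = 3, height: int = 7, width: int = 5) -> bu.ImageStack:
    rng = np.random.default_rng(seed)
    return bu.ImageStack(rng.random((n, height, width)))
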