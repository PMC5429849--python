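import numpy as np
import pytest


@pytest.fixture
def disc_image():
    """Noise-free hypoechoic disc: value 60, radius 20, on background 100."""
    img = np.full((128, 128), 100.0)
    yy, xx = np.mgrid[0:128, 0:128]
    img[(xx - 64) ** 2 + (yy - 64) ** 2 <= 20**2] = 60.0
    truth = img == 60.0
    return img, truth


def random_profile(rng, R, L):
    """Random small integer cost profile, as a CostProfile."""
    from uscut.graphcut import CostProfile, compute_terminal_weights

    costs = rng.integers(0, 21, size=(R, L)).astype(float)
    weights = np.array([compute_terminal_weights(c) for c in costs])
    return CostProfile(costs=costs, terminal_weights=weights)
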