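import numpy as np
import pytest

from edgereg.image import ScalarImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_image(n=128, r=16.0, c=100.0, center=None, spacing=1.0):
    """Single-disk phantom on an n x n unit grid."""
    if center is None:
        center = (n // 2, n // 2)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    data = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r ** 2) * c
    return ScalarImage(data.astype(float).T, spacing=spacing)


@pytest.fixture
def disk128():
    return disk_image()
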