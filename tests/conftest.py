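import numpy as np
import pytest

from ccvpatch.synth_patches import ShapeParams, generate_mask
from ccvpatch.preprocess import trace_contour


@pytest.fixture(scope="session")
def disc_mask():
    """Rasterised disc, radius 10, centred in the 64x64 frame."""
    return generate_mask(ShapeParams(base_radius=10, eccentricity=1.0), seed=1)


@pytest.fixture(scope="session")
def disc_contour(disc_mask):
    return trace_contour(disc_mask)


@pytest.fixture(scope="session")
def square_mask():
    m = np.zeros((64, 64), dtype=bool)
    m[20:30, 20:30] = True
    return m


def brute_force_alternations(signs):
    """Independent pair-scan oracle for the CCV sign-alternation rule:
    zeros inherit the last nonzero sign; count adjacent opposite pairs."""
    inherited = []
    last = 0
    for s in signs:
        if s != 0:
            last = s
        inherited.append(last)
    count = 0
    for a, b in zip(inherited, inherited[1:]):
        if a * b < 0:
            count += 1
    return count
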