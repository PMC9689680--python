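import numpy as np
import pytest

import gelmech as gm


@pytest.fixture(scope="session")
def card() -> gm.MaterialCard:
    return gm.surimi_gel_card()


@pytest.fixture(scope="session")
def geometry() -> gm.RingGeometry:
    return gm.RingGeometry()


@pytest.fixture(scope="session")
def speckle_ref() -> np.ndarray:
    """A 128x128 speckle image shared by the DIC tests."""
    return gm.gen_speckle_image(gm.SpeckleSpec(image_size=(128, 128), seed=3))


@pytest.fixture(scope="session")
def stretch_pair(speckle_ref):
    """Reference plus 5% uniform-stretch frame with its ground truth."""
    stack, truth = gm.warp_sequence(speckle_ref, gm.stretch_schedule([1.0, 1.05]))
    return stack, truth


def matchable_mask(truth, frame, grid_x, grid_y, shape, half):
    """Grid points whose true match stays fully inside the deformed image."""
    X, Y = np.meshgrid(grid_x, grid_y)
    fx, fy = truth.forward(frame, X, Y)
    h, w = shape
    return ((fx >= half) & (fx <= w - 1 - half)
            & (fy >= half) & (fy <= h - 1 - half))
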