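import numpy as np
import pytest

from echotex.io_via import AnnotatedImage, Polygon
from echotex.patches import Patch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    return rng.integers(0, 256, size=(56, 56)).astype(np.uint8)


@pytest.fixture
def constant_patch():
    return np.full((56, 56), 77, dtype=np.uint8)


@pytest.fixture
def labeled_patch(random_patch):
    return Patch(pixels=random_patch, label="HCC", origin=(0, 0), patient_id="p0")


@pytest.fixture
def square_annotated_image():
    """400x400 frame with an axis-aligned square lesion (100,100)-(300,300)."""
    poly = Polygon([(100, 100), (300, 100), (300, 300), (100, 300)])
    return AnnotatedImage(pixels=np.zeros((400, 400), dtype=np.uint8), annotations=[poly])
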