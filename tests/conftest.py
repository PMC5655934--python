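import numpy as np
import pytest

from dxarfa import build_phantom, segment_compartments, detect_landmarks


@pytest.fixture(scope="session")
def phantom():
    """Canonical proximal-femur phantom at the default 0.56 mm spacing."""
    return build_phantom()


@pytest.fixture(scope="session")
def phantom_segmentation(phantom):
    return segment_compartments(phantom.scan)


@pytest.fixture(scope="session")
def phantom_detected_landmarks(phantom, phantom_segmentation):
    return detect_landmarks(phantom.scan, phantom_segmentation)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170413)
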