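import warnings

import numpy as np
import pytest

from emgface import fem
from emgface.features import EMGRecording


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest usable lip model (16 elements) for fast dynamics tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fem.default_lip_model(fem.MeshConfig(nu=4, nv=2, nw=1))


@pytest.fixture(scope="session")
def small_model():
    """Reduced lip model (144 elements) with every muscle populated."""
    return fem.default_lip_model(fem.MeshConfig(nu=12, nv=3, nw=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, fs=2048.0, labels=None, instruction="A"):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(samples.shape[0])]
    return EMGRecording(samples=samples, fs=fs, labels=labels,
                        instruction=instruction)
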