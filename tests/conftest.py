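import numpy as np
import pytest

from abskit.binodal import BinodalModel


@pytest.fixture()
def merchuck_model() -> BinodalModel:
    """A typical salting-out binodal used throughout the tie-line tests."""
    return BinodalModel(a=80.0, b=-0.3, c=5e-5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
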