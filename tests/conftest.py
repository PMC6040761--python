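import numpy as np
import pytest

from glypre.ce import BinMap
from glypre.glycans import GlycanPanel


@pytest.fixture(scope="session")
def panel() -> GlycanPanel:
    return GlycanPanel.default()


@pytest.fixture(scope="session")
def binmap() -> BinMap:
    return BinMap.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
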