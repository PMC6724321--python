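import numpy as np
import pytest

from marimo_machines import make_reference_assembly
from marimo_machines.buoyancy import Column


@pytest.fixture
def reference_assembly():
    return make_reference_assembly()


@pytest.fixture
def column():
    return Column()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
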