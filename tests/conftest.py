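import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gsdir.fixtures import make_case


@pytest.fixture(scope="session")
def case48():
    """One mid-size synthetic registration case shared across tests."""
    return make_case((48, 48, 48), deform_magnitude_vox=3.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
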