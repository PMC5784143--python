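import numpy as np
import pytest
from hypothesis import settings

import pointorder as po

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

SPACING_1 = float(np.sqrt(2.0 / np.sqrt(3.0)))  # hex spacing at unit intensity


@pytest.fixture(scope="session")
def hex_pattern():
    """Perfect triangular lattice, unit intensity, ~14 spacings across."""
    return po.hexagonal_lattice(1.0, po.ObservationWindow(0, 0, 15, 15))


@pytest.fixture(scope="session")
def hex_partition(hex_pattern):
    return po.tessellate(hex_pattern)


@pytest.fixture(scope="session")
def square_pattern():
    return po.square_lattice(1.0, po.ObservationWindow(0, 0, 13, 13))


@pytest.fixture(scope="session")
def csr_pattern():
    return po.csr(1.0, po.ObservationWindow(0, 0, 60, 60), seed=101)


@pytest.fixture(scope="session")
def csr_partition(csr_pattern):
    return po.tessellate(csr_pattern)


@pytest.fixture(scope="session")
def confined_pattern():
    return po.confined_packing(256, po.ObservationWindow(0, 0, 1, 1), seed=1)
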