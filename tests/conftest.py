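import numpy as np
import pytest

from disparikit.simulate import simulate_yule
from disparikit.tree import read_newick


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def yule10():
    return simulate_yule(10, 1.0, seed=42)


@pytest.fixture
def yule70():
    """A fixed 70-tip pure-birth tree rescaled to unit height."""
    return simulate_yule(70, 1.0, seed=7).rescale(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
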