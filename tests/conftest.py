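import numpy as np
import pytest
from hypothesis import settings

import genarch as ga

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); root age 2, ultrametric."""
    return ga.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return ga.read_newick("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);")


@pytest.fixture
def yule_tree():
    return ga.simulate_tree(20, 300.0, rng=7)
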