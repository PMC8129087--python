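import numpy as np
import pytest

from mkevo import read_newick
from mkevo.simulate import make_paper_like_fixture


@pytest.fixture
def cherry():
    return read_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def paper_like():
    """292-tip end-to-end fixture; built once per session (it is not free)."""
    return make_paper_like_fixture(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
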