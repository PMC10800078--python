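import numpy as np
import pytest

from oushift import OUParams, gen_tree, read_newick

CHERRY = "(A:1,B:1);"
THREE_TIP = "((A:1,B:1):1,C:2);"


@pytest.fixture
def cherry():
    return read_newick(CHERRY)


@pytest.fixture
def three_tip():
    return read_newick(THREE_TIP)


@pytest.fixture(scope="session")
def coalescent20():
    return gen_tree("coalescent", 20, seed=11)


@pytest.fixture(scope="session")
def birch100():
    """A 100-taxon pure-birth tree reused by the slower simulations."""
    return gen_tree("pure_birth", 100, seed=42)


@pytest.fixture
def ou_params():
    return OUParams(alpha=1.0, sigma2=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
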