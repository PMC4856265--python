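import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from msnc.network import parse_network  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20160504)


@pytest.fixture
def tree3():
    """3-taxon species tree with a 1.0-CU internal branch."""
    return parse_network("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def net3_1ret():
    """Minimal 1-reticulation network on 3 taxa (hybrid above B)."""
    return parse_network(
        "((A:1,(B:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")


@pytest.fixture
def net4_1ret():
    """4-taxon, 1-reticulation network used across likelihood tests."""
    return parse_network(
        "(((A:1,(B:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1):0.8,D:2.0);")


def random_network(rng, n_leaves, n_ret, max_tries=200):
    """A random valid network built from a random tree by reticulation
    insertion proposals (test helper)."""
    from msnc.moves import MoveConfig, propose_add_reticulation
    from msnc.network import validate
    from msnc.sampler import random_tree

    labels = [chr(65 + i) for i in range(n_leaves)]
    net = random_tree(labels, rng, 1.0)
    cfg = MoveConfig(max_reticulations=n_ret + 1)
    tries = 0
    while net.num_reticulations < n_ret and tries < max_tries:
        res = propose_add_reticulation(net, cfg, rng)
        if res is not None and not validate(res.network):
            net = res.network
        tries += 1
    return net
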