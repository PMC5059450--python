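import numpy as np
import pytest

from paleodiv import phylo_core, synthgen


@pytest.fixture
def cherry_tree():
    return phylo_core.parse_tree("((A,B),C);")


@pytest.fixture
def yule50():
    tree, _ = synthgen.simulate_bd_tree(lam=0.1, mu=0.0, ntips=50, seed=42)
    return tree


def random_dated_tree(seed: int, ntips: int = 20):
    tree, _ = synthgen.simulate_bd_tree(lam=0.1, mu=0.0, ntips=ntips, seed=seed)
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
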