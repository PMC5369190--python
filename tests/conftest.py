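import numpy as np
import pytest

from codonscape import code_model as cm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def canonical_table():
    return cm.canonical_code()


def random_table(rng, model):
    """A random code as a codon -> label dict, via the public generators."""
    if model == "restrictive":
        return cm.expand(cm.random_restrictive(rng))
    g = cm.random_unrestrictive(rng)
    return cm.from_compact(cm.to_compact(g))
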