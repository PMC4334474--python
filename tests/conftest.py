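import numpy as np
import pytest

from planctotaxa import trees as tr


@pytest.fixture
def quartet_tree():
    """The worked 4-tip example: ((A:1,B:1):1,(C:2,D:2):0.5);"""
    return tr.parse_newick("((A:1,B:1):1,(C:2,D:2):0.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
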