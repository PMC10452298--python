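import numpy as np
import pytest

from phylocount import align_data
from phylocount.datasets import five_taxon_tree, toy_table


@pytest.fixture(scope="session")
def five_tree():
    return five_taxon_tree()


@pytest.fixture(scope="session")
def toy_aligned(five_tree):
    """Toy 5-species dataset aligned with the example tree's covariance."""
    data, C = align_data(five_tree, toy_table(), "y", ["x"])
    return data, C


@pytest.fixture()
def rng():
    return np.random.default_rng(20230812)
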