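import numpy as np
import pytest

from gilnet.expression_io import ExpressionMatrix
from gilnet.rmt_network import GILNetwork


def make_network(edges, gil_id="G0001", threshold=0.5):
    """Build a GILNetwork from (a, b) pairs with unit-ish weights."""
    full = [(min(a, b), max(a, b), 0.9) for a, b in edges]
    return GILNetwork(gil_id, sorted(full), threshold)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    values = rng.normal(8.0, 1.0, size=(6, 10))
    return ExpressionMatrix(
        [f"s{i}" for i in range(6)], [f"p{j}" for j in range(10)], values
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic compendium (shared across tests)."""
    from gilnet import synthetic as syn

    matrix, truth = syn.generate_compendium(seed=11)
    return matrix, truth
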