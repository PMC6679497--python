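import pytest

from synscreen import fixtures
from synscreen.network import InteractionNetwork


@pytest.fixture
def path_net() -> InteractionNetwork:
    """The five-node path A-B-C-D-E."""
    return InteractionNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture(scope="session")
def gold_bundle(tmp_path_factory):
    """The hand-computed gold instance, written once per session."""
    root = tmp_path_factory.mktemp("gold")
    return fixtures.gold_instance(root)


def adj_of(net: InteractionNetwork) -> dict:
    """Adjacency-dict view for the brute-force oracles."""
    return {v: set(net.graph.neighbors(v)) for v in net.graph.nodes}
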