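import networkx as nx
import pytest


def _str_graph(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes})


@pytest.fixture
def k5() -> nx.Graph:
    return _str_graph(nx.complete_graph(5))


@pytest.fixture
def star5() -> nx.Graph:
    """Star with 5 leaves: center '0', leaves '1'..'5'."""
    return _str_graph(nx.star_graph(5))


@pytest.fixture
def path4() -> nx.Graph:
    return _str_graph(nx.path_graph(4))


@pytest.fixture
def modular_graph():
    """Small planted-partition fixture shared by the null-model tests."""
    from spokenet.synthetic_data import synth_modular

    return synth_modular(n_modules=4, module_size=50, p_in=0.15, p_out=0.01, seed=42)
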