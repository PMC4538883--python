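import pytest

from treebasenet.generators import (
    add_linking_arcs,
    fixture,
    random_base_tree,
    random_binary_network,
)
from treebasenet.network_core import parse_network

# Frozen generator study conditions: a deterministic mixed pool of sizes.
# random_binary_network carries no tree-basedness guarantee, so the pool
# exercises both positive and negative paths.


def sample_conditions(count):
    return [(3 + i % 4, i % 5, i) for i in range(count)]


def make_sample(n, k, seed):
    return random_binary_network(n, k, seed)


@pytest.fixture(scope="session")
def samples_100():
    return [make_sample(n, k, s) for n, k, s in sample_conditions(100)]


@pytest.fixture(scope="session")
def samples_200():
    return [make_sample(n, k, s) for n, k, s in sample_conditions(200)]


@pytest.fixture(scope="session")
def linked_samples():
    """Networks grown from a known base tree: (tree, network) pairs."""
    out = []
    for i in range(30):
        tree = random_base_tree(3 + i % 4, i)
        out.append((tree, add_linking_arcs(tree, i % 4, seed=1000 + i)))
    return out


@pytest.fixture(scope="session")
def valid_fixture_networks():
    names = (
        "fig1",
        "fig2i",
        "fig2ii",
        "fig2iii",
        "fig3",
        "fig4_wheat",
        "fig5",
        "fig6ii",
        "fig6iii",
        "parallel",
        "double_diamond",
    )
    return {name: fixture(name) for name in names}


@pytest.fixture
def wheat():
    return fixture("fig4_wheat")


@pytest.fixture
def triples():
    """The three rooted triples on {a, b, c}."""
    return {
        "ab|c": parse_network("((a,b),c);", "newick"),
        "ac|b": parse_network("((a,c),b);", "newick"),
        "bc|a": parse_network("((b,c),a);", "newick"),
    }
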