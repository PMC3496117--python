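import networkx as nx
import pytest

from fimodules.network import FINetwork
from fimodules.synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_network,
    generate_pathways,
)


@pytest.fixture
def toy_net() -> FINetwork:
    """Two components: a 5-node ring with a chord, and a 3-node path."""
    g = nx.Graph(
        [
            ("A", "B"),
            ("B", "C"),
            ("C", "D"),
            ("D", "E"),
            ("E", "A"),
            ("A", "C"),
            ("X", "Y"),
            ("Y", "Z"),
        ]
    )
    return FINetwork(g)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the default conditions (seed 1)."""
    cfg = SyntheticConfig(rng_seed=1)
    net, truth = generate_network(cfg)
    mat = generate_expression(net, truth, cfg)
    pathways = generate_pathways(net, truth, rng_seed=1)
    return cfg, net, truth, mat, pathways
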