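import numpy as np
import pytest

from graphmcs.ged import CostModel
from graphmcs.graphs import CONSTANT_LABEL, LabeledGraph


def random_labeled_graph(rng, n_min=1, n_max=6, density=0.4, alphabet=("a", "b", "c"),
                         edge_alphabet=None, graph_id="g"):
    """Small random simple graph with symbolic labels, for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    labels = tuple(alphabet[int(rng.integers(0, len(alphabet)))] for _ in range(n))
    edges, elabs = [], []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < density:
                edges.append((u, v))
                if edge_alphabet:
                    elabs.append(edge_alphabet[int(rng.integers(0, len(edge_alphabet)))])
                else:
                    elabs.append(CONSTANT_LABEL)
    return LabeledGraph(graph_id, labels, tuple(edges), tuple(elabs))


def path_graph(labels, graph_id="path"):
    n = len(labels)
    return LabeledGraph(
        graph_id, tuple(labels),
        tuple((i, i + 1) for i in range(n - 1)),
        (CONSTANT_LABEL,) * (n - 1),
    )


def star_graph(n_leaves, graph_id="star"):
    """Center is node 0."""
    return LabeledGraph(
        graph_id, ("c",) + ("l",) * n_leaves,
        tuple((0, i) for i in range(1, n_leaves + 1)),
        (CONSTANT_LABEL,) * n_leaves,
    )


@pytest.fixture
def cm():
    return CostModel(tau_node=1.0, tau_edge=1.0, alpha=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
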