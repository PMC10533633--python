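"""Synthetic labeled-graph datasets with controllable class separation.

The generator emulates the regime of the molecular / protein / social
benchmarks this framework targets: collections of small simple undirected
graphs (tens of nodes), 2–6 classes, symbolic node labels from a small
alphabet, and class structure expressed through edge density and node-label
composition.  It does not attempt chemically valid molecules or any real
dataset's exact distribution — it exists so every stage of the pipeline is
testable without downloading a benchmark.

``structure_effect`` is the single separation knob: class ``c`` draws its
edge density shifted by ``±structure_effect`` around the base density, and
its node labels from a categorical distribution tilted (odds multiplier
``exp(8 * structure_effect)``) toward a class-specific slice of the
alphabet.  At 0 the class label is independent of graph content; large
values give effectively disjoint label alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import CONSTANT_LABEL, GraphDataset, LabeledGraph

__all__ = ["SyntheticSpec", "generate_dataset", "generate_reduction_probe"]

LABEL_TILT_GAIN = 8.0  # odds multiplier exponent per unit structure_effect


@dataclass(frozen=True)
class SyntheticSpec:
    n_per_class: int = 20
    n_classes: int = 2
    size_range: tuple = (10, 20)
    edge_density: float = 0.25
    label_alphabet: tuple = ("C", "N", "O", "S", "H", "P")
    structure_effect: float = 0.1
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.n_classes < 2:
            raise ValueError("need >= 1 graph per class and >= 2 classes")
        lo, hi = self.size_range
        if not (2 <= lo <= hi):
            raise ValueError(f"bad size_range {self.size_range}")
        if not (0 < self.edge_density < 1):
            raise ValueError("edge_density must lie in (0, 1)")
        if self.structure_effect < 0 or self.noise < 0:
            raise ValueError("structure_effect and noise must be >= 0")

    def class_density(self, c: int) -> float:
        """Edge density for class c: shifted by ±structure_effect across classes."""
        if self.n_classes == 1:
            return self.edge_density
        offset = 2 * c / (self.n_classes - 1) - 1  # in [-1, 1]
        d = self.edge_density + self.structure_effect * offset
        if not (0 < d < 1):
            raise ValueError(
                f"class {c} edge density {d:.3f} outside (0, 1); "
                "reduce structure_effect or move edge_density"
            )
        return d

    def class_label_weights(self, c: int) -> np.ndarray:
        """Categorical node-label weights, tilted toward class c's alphabet slice."""
        a = len(self.label_alphabet)
        w = np.ones(a)
        lo = (c * a) // self.n_classes
        hi = ((c + 1) * a) // self.n_classes
        w[lo:max(hi, lo + 1)] = np.exp(LABEL_TILT_GAIN * self.structure_effect)
        return w / w.sum()


def _random_graph(
    rng: np.random.Generator,
    n: int,
    density: float,
    label_weights: np.ndarray,
    alphabet: tuple,
    noise: float,
    graph_id: str,
) -> LabeledGraph:
    labels = []
    a = len(alphabet)
    for _ in range(n):
        if noise > 0 and rng.random() < noise:
            labels.append(alphabet[int(rng.integers(0, a))])
        else:
            labels.append(alphabet[int(rng.choice(a, p=label_weights))])
    edges = []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < density:
                edges.append((u, v))
    return LabeledGraph(
        graph_id=graph_id,
        node_labels=tuple(labels),
        edges=tuple(edges),
        edge_labels=(CONSTANT_LABEL,) * len(edges),
    )


def generate_dataset(spec: SyntheticSpec) -> GraphDataset:
    """Draw a class-labeled graph dataset; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    densities = [spec.class_density(c) for c in range(spec.n_classes)]  # validate early
    graphs, labels = [], {}
    for c in range(spec.n_classes):
        lw = spec.class_label_weights(c)
        for i in range(spec.n_per_class):
            n = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
            gid = f"syn_c{c}_{i}"
            graphs.append(
                _random_graph(rng, n, densities[c], lw, spec.label_alphabet, spec.noise, gid)
            )
            labels[gid] = f"class{c}"
    return GraphDataset(graphs=graphs, labels=labels, name=f"synthetic-{spec.seed}")


def generate_reduction_probe(n_nodes: int, seed: int = 0) -> LabeledGraph:
    """A connected graph with a designated hub of maximal centrality (node 0).

    The hub is adjacent to every other node; the remaining nodes form a
    sparse ring with a few chords, so the hub strictly dominates both the
    degree-propagating and the shortest-path centrality rankings and
    survives any reduction keeping at least two nodes (lambda >= 2/n).
    """
    if n_nodes < 2:
        raise ValueError("probe needs >= 2 nodes")
    rng = np.random.default_rng(seed)
    edges = {(0, v) for v in range(1, n_nodes)}
    leaves = list(range(1, n_nodes))
    for i, u in enumerate(leaves[:-1]):  # ring keeps the periphery connected
        if rng.random() < 0.5:
            edges.add((u, leaves[i + 1]))
    return LabeledGraph(
        graph_id=f"probe_{n_nodes}_{seed}",
        node_labels=tuple("hub" if i == 0 else "leaf" for i in range(n_nodes)),
        edges=tuple(sorted(edges)),
        edge_labels=(CONSTANT_LABEL,) * len(edges),
    )
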