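"""Graph edit distance: cost model, bipartite (BP) approximation, exact oracle.

Graph edit distance (GED) is the minimum total cost of node/edge insertions,
deletions and substitutions transforming one graph into another.  Exact GED
is NP-complete; the BP approximation solves, in cubic time, a linear sum
assignment problem over the two node sets augmented with deletion/insertion
slots, where each node carries its local edge structure.  The node
assignment induces a complete edit path whose cost upper-bounds the exact
distance.

Costs are parameterized by :class:`CostModel`: ``tau_node`` / ``tau_edge``
for insertions and deletions, substitution functions on labels, and ``alpha``
in (0, 1) weighting node against edge operations — a node operation costs
``alpha * c``, an edge operation ``(1 - alpha) * c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .graphs import GraphDataset, LabeledGraph

__all__ = [
    "CostModel",
    "EditAssignment",
    "DistanceMatrix",
    "DELETE",
    "bp_cost_matrix",
    "bp_ged",
    "exact_ged",
    "induced_edit_cost",
    "pairwise_distances",
]

DELETE = "<delete>"

EXACT_GED_MAX_NODES = 12  # |V1| + |V2| guard for the exhaustive oracle


def _is_numeric(label) -> bool:
    return isinstance(label, (int, float)) or (
        isinstance(label, tuple) and all(isinstance(x, (int, float)) for x in label)
    )


def _as_vector(label) -> np.ndarray:
    if isinstance(label, tuple):
        return np.asarray(label, dtype=float)
    return np.asarray([label], dtype=float)


@dataclass(frozen=True)
class CostModel:
    """Edit-operation costs.

    With the default substitution functions, symbolic labels use a Dirac
    cost (0 if equal, else ``2 * tau`` so a substitution never trivially
    exceeds deletion plus insertion) and numeric labels/vectors use the
    Euclidean distance.  Custom functions must be symmetric and zero on
    identical labels.
    """

    tau_node: float = 1.0
    tau_edge: float = 1.0
    alpha: float = 0.5
    node_sub: object = None  # callable(label, label) -> cost, or None for default
    edge_sub: object = None

    def __post_init__(self):
        if self.tau_node < 0 or self.tau_edge < 0:
            raise ValueError("tau costs must be nonnegative")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    def _default_sub(self, l1, l2, tau: float) -> float:
        if l1 == l2:
            return 0.0
        if _is_numeric(l1) and _is_numeric(l2):
            v1, v2 = _as_vector(l1), _as_vector(l2)
            if v1.shape == v2.shape:
                return float(np.linalg.norm(v1 - v2))
        return 2.0 * tau

    def node_cost(self, l1, l2) -> float:
        if self.node_sub is not None:
            return self.node_sub(l1, l2)
        return self._default_sub(l1, l2, self.tau_node)

    def edge_cost(self, l1, l2) -> float:
        if self.edge_sub is not None:
            return self.edge_sub(l1, l2)
        return self._default_sub(l1, l2, self.tau_edge)

    def scaled(self, c: float) -> "CostModel":
        """Scale both tau costs by ``c`` (substitution functions untouched)."""
        return CostModel(
            tau_node=c * self.tau_node,
            tau_edge=c * self.tau_edge,
            alpha=self.alpha,
            node_sub=self.node_sub,
            edge_sub=self.edge_sub,
        )


@dataclass(frozen=True)
class EditAssignment:
    """A node mapping of g1 onto g2 with deletions and insertions.

    ``mapping[u]`` is the image of g1 node ``u`` (a g2 node index) or
    :data:`DELETE`; ``inserted`` are the g2 nodes with no preimage.
    """

    mapping: tuple
    inserted: tuple
    cost: float

    def __post_init__(self):
        images = [m for m in self.mapping if m != DELETE]
        if len(set(images)) != len(images):
            raise ValueError("assignment not injective on non-deleted nodes")
        if set(images) & set(self.inserted):
            raise ValueError("inserted nodes overlap assignment images")


def _node_sub_matrix(g1: LabeledGraph, g2: LabeledGraph, cm: CostModel) -> np.ndarray:
    """Node-label substitution costs, vectorized for the default cost model."""
    l1, l2 = g1.node_labels, g2.node_labels
    if cm.node_sub is None and all(isinstance(x, str) for x in l1 + l2):
        a1 = np.array(l1, dtype=object)
        a2 = np.array(l2, dtype=object)
        return np.where(a1[:, None] == a2[None, :], 0.0, 2.0 * cm.tau_node)
    if cm.node_sub is None and all(_is_numeric(x) for x in l1 + l2):
        v1 = np.array([_as_vector(x) for x in l1], dtype=float)
        v2 = np.array([_as_vector(x) for x in l2], dtype=float)
        if v1.shape[1] == v2.shape[1]:
            return cdist(v1, v2)
    out = np.empty((len(l1), len(l2)))
    for i, a in enumerate(l1):
        for j, b in enumerate(l2):
            out[i, j] = cm.node_cost(a, b)
    return out


def _edge_multiset_cost(labels1: list, labels2: list, cm: CostModel) -> float:
    """Optimal assignment cost between two incident-edge label multisets."""
    d1, d2 = len(labels1), len(labels2)
    if d1 == 0 or d2 == 0:
        return (d1 + d2) * cm.tau_edge
    uniq = set(labels1) | set(labels2)
    if len(uniq) == 1:  # identical labels: only the degree difference costs
        return abs(d1 - d2) * cm.tau_edge
    size = d1 + d2
    big = cm.tau_edge * size + sum(
        cm.edge_cost(a, b) for a in labels1 for b in labels2
    ) + 1.0
    c = np.full((size, size), big)
    for i, a in enumerate(labels1):
        for j, b in enumerate(labels2):
            c[i, j] = cm.edge_cost(a, b)
    for i in range(d1):
        c[i, d2 + i] = cm.tau_edge
    for j in range(d2):
        c[d1 + j, j] = cm.tau_edge
    c[d1:, d2:] = 0.0
    ri, ci = linear_sum_assignment(c)
    return float(c[ri, ci].sum())


def bp_cost_matrix(g1: LabeledGraph, g2: LabeledGraph, cm: CostModel) -> np.ndarray:
    """The (|V1|+|V2|) square BP cost matrix.

    Quadrants: substitutions (node-label cost plus the optimal assignment of
    the incident-edge label multisets) top-left; deletions of g1 nodes with
    their incident edges on the top-right diagonal; insertions of g2 nodes
    bottom-left; zeros bottom-right.  Off-diagonal deletion/insertion cells
    carry a finite big-M (total cost sum + 1) so the exact assignment solver
    stays applicable while those cells are never selected.
    """
    n1, n2 = g1.n_nodes, g2.n_nodes
    a = cm.alpha
    sub = a * _node_sub_matrix(g1, g2, cm) if n1 and n2 else np.zeros((n1, n2))
    deg1, deg2 = g1.degrees(), g2.degrees()

    inc1 = [g1.incident_edge_labels(u) for u in range(n1)]
    inc2 = [g2.incident_edge_labels(v) for v in range(n2)]
    constant_edges = len(set().union(*(set(x) for x in inc1 + inc2), set())) <= 1
    if n1 and n2:
        if constant_edges:
            sub = sub + (1 - a) * cm.tau_edge * np.abs(
                deg1[:, None].astype(float) - deg2[None, :]
            )
        else:
            edge_part = np.empty((n1, n2))
            for i in range(n1):
                for j in range(n2):
                    edge_part[i, j] = _edge_multiset_cost(inc1[i], inc2[j], cm)
            sub = sub + (1 - a) * edge_part

    del_diag = a * cm.tau_node + (1 - a) * deg1 * cm.tau_edge
    ins_diag = a * cm.tau_node + (1 - a) * deg2 * cm.tau_edge
    big = float(sub.sum() + del_diag.sum() + ins_diag.sum() + 1.0)

    c = np.zeros((n1 + n2, n1 + n2))
    c[:n1, :n2] = sub
    c[:n1, n2:] = big
    c[:n1, n2:][np.arange(n1), np.arange(n1)] = del_diag
    c[n1:, :n2] = big
    c[n1:, :n2][np.arange(n2), np.arange(n2)] = ins_diag
    return c


def induced_edit_cost(
    g1: LabeledGraph, g2: LabeledGraph, mapping: tuple, cm: CostModel
) -> float:
    """Cost of the complete edit path induced by a node mapping.

    ``mapping[u]`` is a g2 node or :data:`DELETE`.  An edge of g1 maps to an
    edge of g2 iff both endpoint images are adjacent in g2 (substitution);
    otherwise it is deleted.  g2 edges with no preimage are inserted.
    """
    a = cm.alpha
    node_cost = 0.0
    images = set()
    for u, m in enumerate(mapping):
        if m == DELETE:
            node_cost += cm.tau_node
        else:
            node_cost += cm.node_cost(g1.node_labels[u], g2.node_labels[m])
            images.add(m)
    node_cost += cm.tau_node * (g2.n_nodes - len(images))

    e2_labels = dict(zip(g2.edges, g2.edge_labels))
    covered = set()
    edge_cost = 0.0
    for (u, v), lab in zip(g1.edges, g1.edge_labels):
        mu, mv = mapping[u], mapping[v]
        if mu != DELETE and mv != DELETE:
            key = (mu, mv) if mu < mv else (mv, mu)
            if key in e2_labels:
                edge_cost += cm.edge_cost(lab, e2_labels[key])
                covered.add(key)
                continue
        edge_cost += cm.tau_edge  # deletion
    edge_cost += cm.tau_edge * (len(e2_labels) - len(covered))  # insertions
    return a * node_cost + (1 - a) * edge_cost


def bp_ged(g1: LabeledGraph, g2: LabeledGraph, cm: CostModel) -> tuple:
    """BP approximation of GED: optimal node assignment, induced edit cost.

    Returns ``(distance, assignment)``.  The distance is the cost of the
    edit path induced by the optimal solution of the linear sum assignment
    problem on :func:`bp_cost_matrix`; it upper-bounds exact GED.
    """
    n1, n2 = g1.n_nodes, g2.n_nodes
    if n1 == 0 and n2 == 0:
        return 0.0, EditAssignment((), (), 0.0)
    c = bp_cost_matrix(g1, g2, cm)
    rows, cols = linear_sum_assignment(c)
    mapping = [DELETE] * n1
    for r, col in zip(rows, cols):
        if r < n1 and col < n2:
            mapping[r] = int(col)
    mapping = tuple(mapping)
    images = {m for m in mapping if m != DELETE}
    inserted = tuple(v for v in range(n2) if v not in images)
    dist = induced_edit_cost(g1, g2, mapping, cm)
    return dist, EditAssignment(mapping=mapping, inserted=inserted, cost=dist)


def exact_ged(g1: LabeledGraph, g2: LabeledGraph, cm: CostModel) -> float:
    """Exact GED by exhaustive search over node mappings with deletions.

    Depth-first branch-and-bound over all injective partial mappings of g1
    nodes onto g2 nodes; edge costs are accumulated incrementally against
    already-placed nodes.  Guarded to ``|V1| + |V2| <= 12`` — this is a
    small-instance verification oracle, not a production matcher.
    """
    n1, n2 = g1.n_nodes, g2.n_nodes
    if n1 + n2 > EXACT_GED_MAX_NODES:
        raise ValueError(
            f"exact_ged guard exceeded: |V1|+|V2| = {n1 + n2} > {EXACT_GED_MAX_NODES}"
        )
    a = cm.alpha
    adj1 = {}
    for (u, v), lab in zip(g1.edges, g1.edge_labels):
        adj1[(u, v)] = adj1[(v, u)] = lab
    adj2 = {}
    for (u, v), lab in zip(g2.edges, g2.edge_labels):
        adj2[(u, v)] = adj2[(v, u)] = lab

    # all-delete / all-insert edit path: always feasible initial upper bound
    best = a * cm.tau_node * (n1 + n2) + (1 - a) * cm.tau_edge * (g1.n_edges + g2.n_edges)

    nsub = _node_sub_matrix(g1, g2, cm) if n1 and n2 else np.zeros((n1, n2))
    placed: list = []  # (u, image or DELETE)

    def leaf_cost(used_images: set) -> float:
        extra = a * cm.tau_node * (n2 - len(used_images))
        for (u, v) in g2.edges:
            if u not in used_images or v not in used_images:
                extra += (1 - a) * cm.tau_edge
        return extra

    def recurse(u: int, cost: float, used: set):
        nonlocal best
        if cost >= best:
            return
        if u == n1:
            total = cost + leaf_cost(used)
            if total < best:
                best = total
            return
        choices = [v for v in range(n2) if v not in used] + [DELETE]
        for v in choices:
            step = a * (cm.tau_node if v == DELETE else nsub[u, v])
            for (w, img) in placed:
                e1 = adj1.get((u, w))
                has_e1 = (u, w) in adj1
                if v == DELETE or img == DELETE:
                    if has_e1:
                        step += (1 - a) * cm.tau_edge
                    continue
                has_e2 = (v, img) in adj2
                if has_e1 and has_e2:
                    step += (1 - a) * cm.edge_cost(e1, adj2[(v, img)])
                elif has_e1 or has_e2:
                    step += (1 - a) * cm.tau_edge
            placed.append((u, v))
            if v != DELETE:
                used.add(v)
            recurse(u + 1, cost + step, used)
            placed.pop()
            if v != DELETE:
                used.discard(v)

    recurse(0, 0.0, set())
    return float(best)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise BP-GED values; rows are query graphs, columns references."""

    row_ids: list
    col_ids: list
    values: np.ndarray
    level: tuple = ("original", 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("distance matrix shape does not match id lists")
        if np.any(self.values < 0):
            raise ValueError("negative distance")

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        df.to_csv(path, sep="\t")
        meta = Path(str(path) + ".meta")
        meta.write_text(f"measure\t{self.level[0]}\nlambda\t{self.level[1]}\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        level = ("original", 1.0)
        meta = Path(str(path) + ".meta")
        if meta.exists():
            kv = dict(line.split("\t") for line in meta.read_text().splitlines() if line)
            level = (kv.get("measure", "original"), float(kv.get("lambda", 1.0)))
        return cls(
            row_ids=list(df.index.astype(str)),
            col_ids=list(df.columns.astype(str)),
            values=df.to_numpy(),
            level=level,
        )


def pairwise_distances(
    queries: GraphDataset,
    references: GraphDataset,
    cm: CostModel,
    level: tuple = ("original", 1.0),
) -> DistanceMatrix:
    """BP-GED between every query and every reference graph.

    For each unordered pair, BP runs once on the pair sorted by graph_id and
    the value fills both cells, which makes a self-distance matrix exactly
    symmetric; self-distances are exactly zero.
    """
    cache: dict = {}
    by_id = {g.graph_id: g for g in list(queries.graphs) + list(references.graphs)}

    def dist(ida: str, idb: str) -> float:
        if ida == idb:
            return 0.0
        key = (ida, idb) if ida < idb else (idb, ida)
        if key not in cache:
            cache[key] = bp_ged(by_id[key[0]], by_id[key[1]], cm)[0]
        return cache[key]

    values = np.empty((len(queries), len(references)))
    for i, gq in enumerate(queries.graphs):
        for j, gr in enumerate(references.graphs):
            values[i, j] = dist(gq.graph_id, gr.graph_id)
    return DistanceMatrix(
        row_ids=queries.graph_ids,
        col_ids=references.graph_ids,
        values=values,
        level=level,
    )
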