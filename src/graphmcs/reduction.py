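"""Centrality-based graph reduction and reduced-subspace construction.

Reduction keeps the ``floor(lambda * |V|)`` most central nodes of each graph
(and the edges among them) at each reduction factor ``lambda``.  Two node
centrality measures are provided:

* **PageRank** — the fixed point of ``x = damping * A D^-1 x + beta * 1``
  with ``D_ii = max(degree(v_i), 1)``, solved by damped fixed-point
  iteration.  With ``beta = 1`` the scores are unnormalized (an isolated
  node scores exactly 1).
* **Betweenness** — for each node, the number of unordered node pairs
  ``{s, t}`` (endpoints excluded, ``t`` reachable from ``s``) such that the
  node lies on at least one shortest ``s``–``t`` path, i.e. a binary
  membership count rather than the fractional Brandes measure.  The Brandes
  variant is available behind ``variant="brandes"``.

Scores are always computed once on the original graph and reused for every
reduction factor, which makes the retained node sets nested across the
lambda schedule.  Score ties are broken by ascending node index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import GraphDataset, LabeledGraph

__all__ = [
    "CentralityScores",
    "ReductionPlan",
    "SubspaceStack",
    "DEFAULT_LAMBDAS",
    "pagerank_scores",
    "betweenness_scores",
    "centrality_scores",
    "keep_count",
    "reduce_graph",
    "build_subspaces",
]

#: the evaluated reduction-factor schedule (1.0 = the original graph space)
DEFAULT_LAMBDAS = (1.0, 0.8, 0.6, 0.4, 0.2)

MEASURES = ("pagerank", "betweenness")


@dataclass(frozen=True)
class CentralityScores:
    graph_id: str
    measure: str
    score: np.ndarray  # score[i] for node i
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.score)):
            raise ValueError(f"{self.graph_id}: non-finite centrality score")

    def ranking(self) -> np.ndarray:
        """Node indices from most to least central; ties by ascending index."""
        order = np.argsort(-np.asarray(self.score), kind="stable")
        return order


def pagerank_scores(
    g: LabeledGraph,
    damping: float = 0.85,
    beta: float = 1.0,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> CentralityScores:
    """Unnormalized PageRank scores via damped fixed-point iteration.

    Iterates ``x <- damping * A D^-1 x + beta * 1`` from the all-ones vector
    until the infinity-norm residual drops below ``tol``.  ``damping < 1``
    guarantees contraction, since ``A D^-1`` has unit column sums on the
    non-isolated columns.
    """
    if g.n_nodes == 0:
        raise ValueError("pagerank on empty graph")
    if not (0 < damping < 1):
        raise ValueError(f"damping must lie in (0,1), got {damping}")
    a = g.adjacency()
    d = np.maximum(g.degrees(), 1).astype(float)
    m = a / d[np.newaxis, :]  # A D^-1 (column-normalized)
    x = np.ones(g.n_nodes)
    for _ in range(max_iter):
        fx = damping * (m @ x) + beta
        if np.max(np.abs(fx - x)) <= tol:
            break  # x itself satisfies the fixed-point residual bound
        x = fx
    else:
        resid = np.max(np.abs(damping * (m @ x) + beta - x))
        raise RuntimeError(f"pagerank failed to converge: residual {resid:.3e}")
    return CentralityScores(
        graph_id=g.graph_id,
        measure="pagerank",
        score=x,
        parameters={"damping": damping, "beta": beta, "tol": tol, "max_iter": max_iter},
    )


def betweenness_scores(g: LabeledGraph, variant: str = "binary") -> CentralityScores:
    """Shortest-path membership counts (or Brandes centrality) per node.

    The default ``binary`` variant counts, for node ``v``, the unordered
    pairs ``{s, t}`` with ``s != v != t`` and ``t`` reachable from ``s`` for
    which ``d(s,v) + d(v,t) == d(s,t)`` over unweighted hop distances —
    membership in at least one shortest path, not the path-fraction sum.
    """
    if g.n_nodes == 0:
        raise ValueError("betweenness on empty graph")
    if variant == "brandes":
        bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
        score = np.array([bc[i] for i in range(g.n_nodes)])
        return CentralityScores(g.graph_id, "betweenness", score, {"variant": variant})
    if variant != "binary":
        raise ValueError(f"unknown betweenness variant {variant!r}")
    nxg = g.to_networkx()
    dist = {s: lengths for s, lengths in nx.all_pairs_shortest_path_length(nxg)}
    n = g.n_nodes
    score = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in range(n):
                if v == s or v == t:
                    continue
                if v in dist[s] and t in dist[v] and dist[s][v] + dist[v][t] == d_st:
                    score[v] += 1
    return CentralityScores(g.graph_id, "betweenness", score, {"variant": variant})


def centrality_scores(g: LabeledGraph, measure: str, **kwargs) -> CentralityScores:
    if measure == "pagerank":
        return pagerank_scores(g, **kwargs)
    if measure == "betweenness":
        return betweenness_scores(g, **kwargs)
    raise ValueError(f"unknown centrality measure {measure!r}")


def keep_count(lam: float, n: int) -> int:
    """Number of nodes retained at reduction factor ``lam``: ``floor(lam * n)``."""
    if not (0 < lam <= 1):
        raise ValueError(f"reduction factor must lie in (0, 1], got {lam}")
    if n < 0:
        raise ValueError("negative node count")
    return int(np.floor(lam * n + 1e-12))


def reduce_graph(g: LabeledGraph, scores: CentralityScores, lam: float) -> LabeledGraph:
    """Keep the ``floor(lam*|V|)`` highest-scoring nodes and their induced edges.

    Ties in score are broken by ascending node index.  Isolated nodes and
    disconnected components in the output are legal.
    """
    if scores.graph_id != g.graph_id or len(scores.score) != g.n_nodes:
        raise ValueError(
            f"scores for {scores.graph_id!r} ({len(scores.score)} nodes) do not "
            f"match graph {g.graph_id!r} ({g.n_nodes} nodes)"
        )
    k = keep_count(lam, g.n_nodes)
    keep = sorted(scores.ranking()[:k].tolist())
    return g.induced_subgraph(keep)


@dataclass(frozen=True)
class ReductionPlan:
    """Which centrality measures and reduction factors define the subspaces.

    ``levels()`` yields ``(measure, lam)`` pairs; ``lam = 1.0`` is the
    original graph space and is emitted once even when both measures are
    requested (reduction at 1.0 is measure-independent).
    """

    measures: tuple = ("pagerank",)
    lambdas: tuple = DEFAULT_LAMBDAS

    def __post_init__(self):
        if not self.measures or not self.lambdas:
            raise ValueError("empty reduction plan")
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}")
        if any(not (0 < l <= 1) for l in self.lambdas):
            raise ValueError("lambdas must lie in (0, 1]")
        if list(self.lambdas) != sorted(set(self.lambdas), reverse=True):
            raise ValueError("lambdas must be strictly decreasing")

    def levels(self) -> list:
        out = []
        emitted_original = False
        for m in self.measures:
            for lam in self.lambdas:
                if lam == 1.0:
                    if emitted_original:
                        continue
                    emitted_original = True
                    out.append(("original", 1.0))
                else:
                    out.append((m, lam))
        return out


@dataclass
class SubspaceStack:
    """The reduced copies of one dataset, one :class:`GraphDataset` per level."""

    source: str
    levels: dict  # (measure, lam) -> GraphDataset

    def level_keys(self) -> list:
        return list(self.levels.keys())

    def __getitem__(self, key):
        return self.levels[key]

    def __len__(self):
        return len(self.levels)


def build_subspaces(ds: GraphDataset, plan: ReductionPlan) -> SubspaceStack:
    """Reduce every graph of ``ds`` at every level of ``plan``.

    Centrality scores are computed once per (graph, measure) on the original
    graph and reused across all lambdas, which guarantees nesting of the
    retained node sets: ``V_0.2 ⊆ V_0.4 ⊆ ... ⊆ V_1.0``.
    """
    keys = plan.levels()
    score_cache: dict = {}
    levels: dict = {}
    for (measure, lam) in keys:
        if lam == 1.0:
            levels[(measure, lam)] = ds
            continue
        graphs = []
        for g in ds.graphs:
            ck = (measure, g.graph_id)
            if ck not in score_cache:
                score_cache[ck] = centrality_scores(g, measure)
            graphs.append(reduce_graph(g, score_cache[ck], lam))
        levels[(measure, lam)] = GraphDataset(
            graphs=graphs, labels=dict(ds.labels), name=f"{ds.name}@{measure}:{lam}"
        )
    return SubspaceStack(source=ds.name, levels=levels)
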