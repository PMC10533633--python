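"""Weight-vector search (grid and genetic algorithm) and hyperparameter validation.

The ensemble weights live on the simplex, so both optimizers search
normalized vectors.  Grid search enumerates every Cartesian point of an
11-value per-weight grid (``1.0, 0.9, ..., 0.0`` by default), drops the
all-zero point, normalizes and deduplicates.  The genetic algorithm evolves
a population of simplex points with tournament selection, single-point
crossover and multiplicative log-normal mutation, renormalizing after every
operator; elitism makes the best-fitness history non-decreasing.

``validate_hyperparams`` reproduces the protocol that fixes the edit-cost
weighting ``alpha`` and the neighbor count ``k`` by stratified fivefold
cross-validation on the original (unreduced) graphs; the selected pair is
then reused on every reduced subspace.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ensemble import KnnConfig, WeightVector, accuracy, knn_predict
from .ged import CostModel, pairwise_distances
from .graphs import GraphDataset

__all__ = [
    "GridSpec",
    "GAConfig",
    "Chromosome",
    "grid_size",
    "enumerate_weight_grid",
    "grid_search",
    "ga_optimize",
    "validate_hyperparams",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_K_GRID",
]

DEFAULT_GRID_VALUES = tuple(round(1.0 - 0.1 * i, 1) for i in range(11))  # 1.0 ... 0.0
DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
DEFAULT_K_GRID = (1, 3, 5)


@dataclass(frozen=True)
class GridSpec:
    n_spaces: int
    values: tuple = DEFAULT_GRID_VALUES

    def __post_init__(self):
        if self.n_spaces < 1 or not self.values:
            raise ValueError("invalid grid spec")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    mutation_prob: float = 0.1
    generations: int = 100
    seed: int = 0
    elitism: int = 1
    mutation_scale: float = 0.5  # std of the log-normal gene perturbation

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.mutation_prob <= 1):
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")


@dataclass
class Chromosome:
    genes: WeightVector
    fitness: float | None = None


def grid_size(spec: GridSpec) -> int:
    """Raw Cartesian count |values|^n_spaces (before normalization/dedup)."""
    return len(spec.values) ** spec.n_spaces


def enumerate_weight_grid(spec: GridSpec):
    """Yield every normalized, deduplicated non-zero grid point, in a
    deterministic order (Cartesian order of first occurrence)."""
    seen = set()
    for point in itertools.product(spec.values, repeat=spec.n_spaces):
        s = sum(point)
        if s <= 0:
            continue
        w = tuple(round(x / s, 12) for x in point)
        if w in seen:
            continue
        seen.add(w)
        yield WeightVector.normalized(point)


def grid_search(evaluate, spec: GridSpec) -> tuple:
    """Exhaustive argmax of ``evaluate`` over the weight grid.

    Ties keep the first-encountered vector.  Returns ``(best, fitness)``.
    """
    best_w, best_f = None, -np.inf
    for w in enumerate_weight_grid(spec):
        f = evaluate(w)
        if f > best_f:
            best_w, best_f = w, f
    if best_w is None:
        raise ValueError("empty weight grid")
    return best_w, best_f


def _random_simplex(rng: np.random.Generator, n: int) -> WeightVector:
    raw = rng.random(n) + 1e-12
    return WeightVector.normalized(raw)


def _mutate(rng: np.random.Generator, w: WeightVector, p: float, scale: float) -> WeightVector:
    genes = np.asarray(w.as_array())
    mask = rng.random(len(genes)) < p
    if mask.any():
        factors = np.exp(rng.normal(0.0, scale, size=len(genes)))
        genes = np.where(mask, genes * factors, genes)
    genes = np.clip(genes, 1e-6, 1.0)
    return WeightVector.normalized(genes)


def _crossover(rng: np.random.Generator, a: WeightVector, b: WeightVector) -> tuple:
    n = len(a)
    if n == 1:
        return a, b
    site = int(rng.integers(1, n))  # cut between site-1 and site
    ga, gb = a.as_array(), b.as_array()
    child1 = np.concatenate([ga[:site], gb[site:]])
    child2 = np.concatenate([gb[:site], ga[site:]])
    child1 = np.clip(child1, 1e-12, None)
    child2 = np.clip(child2, 1e-12, None)
    return WeightVector.normalized(child1), WeightVector.normalized(child2)


def ga_optimize(evaluate, n_spaces: int, cfg: GAConfig = GAConfig()) -> tuple:
    """Genetic algorithm over simplex weight vectors.

    Per generation: fitness evaluation, elitist carry-over of the best
    ``cfg.elitism`` chromosomes, tournament selection (size 2), single-point
    crossover at a uniform random site, per-gene mutation with probability
    ``cfg.mutation_prob`` (multiplicative log-normal perturbation); children
    are renormalized onto the simplex after every operator.

    Returns ``(best_weights, best_fitness, history)`` where ``history`` is
    the per-generation all-time-best fitness (non-decreasing when
    ``elitism >= 1``).
    """
    if n_spaces < 1:
        raise ValueError("n_spaces must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    pop = [Chromosome(_random_simplex(rng, n_spaces)) for _ in range(cfg.population_size)]
    best: Chromosome | None = None
    history: list = []

    def fit(c: Chromosome) -> float:
        if c.fitness is None:
            c.fitness = float(evaluate(c.genes))
        return c.fitness

    def tournament() -> Chromosome:
        i, j = rng.integers(0, len(pop), size=2)
        a, b = pop[int(i)], pop[int(j)]
        return a if fit(a) >= fit(b) else b

    for _ in range(cfg.generations):
        pop.sort(key=fit, reverse=True)
        if best is None or fit(pop[0]) > best.fitness:
            best = Chromosome(pop[0].genes, fit(pop[0]))
        history.append(best.fitness)
        nxt = [Chromosome(c.genes, c.fitness) for c in pop[: cfg.elitism]]
        while len(nxt) < cfg.population_size:
            p1, p2 = tournament(), tournament()
            c1, c2 = _crossover(rng, p1.genes, p2.genes)
            nxt.append(Chromosome(_mutate(rng, c1, cfg.mutation_prob, cfg.mutation_scale)))
            if len(nxt) < cfg.population_size:
                nxt.append(Chromosome(_mutate(rng, c2, cfg.mutation_prob, cfg.mutation_scale)))
        pop = nxt
    # final population may contain a new best
    pop.sort(key=fit, reverse=True)
    if best is None or fit(pop[0]) > best.fitness:
        best = Chromosome(pop[0].genes, fit(pop[0]))
    return best.genes, float(best.fitness), history


def validate_hyperparams(
    train: GraphDataset,
    alphas: tuple = DEFAULT_ALPHA_GRID,
    ks: tuple = DEFAULT_K_GRID,
    folds: int = 5,
    seed: int = 0,
    base_cost: CostModel = CostModel(),
) -> tuple:
    """Select (alpha, k) by stratified k-fold CV accuracy on the original graphs.

    For each candidate alpha, pairwise BP distances are recomputed (the cost
    matrix depends on alpha); each fold classifies its held-out graphs
    against the remaining training graphs with every candidate k.  The
    argmax pair is returned; ties prefer the smaller k, then smaller alpha.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids = np.array(train.graph_ids, dtype=object)
    y = np.array([str(train.labels[g]) for g in ids], dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"smallest class has {counts.min()} members; need >= {folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_pairs = list(skf.split(ids, y))

    scores: dict = {}
    for alpha in alphas:
        cm = CostModel(
            tau_node=base_cost.tau_node,
            tau_edge=base_cost.tau_edge,
            alpha=alpha,
            node_sub=base_cost.node_sub,
            edge_sub=base_cost.edge_sub,
        )
        full = pairwise_distances(train, train, cm)
        vals = full.values
        for tr_idx, va_idx in fold_pairs:
            block_vals = vals[np.ix_(va_idx, tr_idx)]
            from .ged import DistanceMatrix

            block = DistanceMatrix(
                row_ids=[ids[i] for i in va_idx],
                col_ids=[ids[i] for i in tr_idx],
                values=block_vals,
            )
            tr_labels = {ids[i]: train.labels[ids[i]] for i in tr_idx}
            truth = {ids[i]: train.labels[ids[i]] for i in va_idx}
            for k in ks:
                if k > len(tr_idx):
                    continue
                pred = knn_predict(tr_labels, block, KnnConfig(k=k, alpha=alpha))
                scores.setdefault((alpha, k), []).append(accuracy(pred, truth))

    if not scores:
        raise ValueError("no feasible (alpha, k) pair for these folds")
    mean = {pair: float(np.mean(v)) for pair, v in scores.items()}
    best = max(mean.values())
    feas = [p for p, m in mean.items() if m >= best - 1e-12]
    feas.sort(key=lambda p: (p[1], p[0]))  # smaller k, then smaller alpha
    return feas[0]
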