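"""Model/Results objects for the reduced-subspace ensemble classifier.

:class:`GraphEnsembleClassifier` is the model: it is constructed from a
train/validation/test split (or a whole dataset, split on the fly) and an
:class:`ExperimentConfig`, and its :meth:`~GraphEnsembleClassifier.fit`
executes the three-step pipeline — centrality reduction into subspaces,
pairwise BP graph edit distances per subspace, and weight optimization of
the linear combination on the validation set.  The returned
:class:`GraphEnsembleResults` carries the fitted weights, per-subspace
validation accuracies, the once-evaluated test accuracy, per-level GED
wall-clock, and a ``summary()`` table.

Experiment names follow the <reduction>-<combination>-<optimizer> scheme:
PR / BW / PR+BW crossed with CoD / CoP and GS / GA — ten valid setups, since
the nine-subspace PR+BW search space is only tractable for the GA.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ensemble import (
    KnnConfig,
    PredictionVector,
    WeightVector,
    accuracy,
    combine_distances,
    combine_predictions,
    knn_predict,
)
from .ged import CostModel, DistanceMatrix, pairwise_distances
from .graphs import DatasetSplit, GraphDataset, stratified_split
from .optimize import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_K_GRID,
    GAConfig,
    GridSpec,
    ga_optimize,
    grid_search,
    validate_hyperparams,
)
from .reduction import DEFAULT_LAMBDAS, ReductionPlan, build_subspaces

__all__ = ["ExperimentConfig", "GraphEnsembleClassifier", "GraphEnsembleResults", "ConfigError"]


class ConfigError(ValueError):
    pass


_REDUCTIONS = {
    "PR": ("pagerank",),
    "BW": ("betweenness",),
    "PR+BW": ("pagerank", "betweenness"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental setup: reduction x combination x optimization.

    ``alpha``/``k`` left as None triggers the fivefold cross-validation
    protocol on the training set; explicit values skip it.
    """

    reduction: str = "PR"          # PR | BW | PR+BW
    combination: str = "CoD"       # CoD | CoP
    optimizer: str = "GA"          # GS | GA
    lambdas: tuple = DEFAULT_LAMBDAS
    alpha: float | None = None
    k: int | None = None
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    k_grid: tuple = DEFAULT_K_GRID
    cv_folds: int = 5
    tau_node: float = 1.0
    tau_edge: float = 1.0
    ga: GAConfig = field(default_factory=GAConfig)
    grid_values: tuple = GridSpec(1).values
    seed: int = 0

    def __post_init__(self):
        if self.reduction not in _REDUCTIONS:
            raise ConfigError(f"unknown reduction {self.reduction!r} (PR, BW, PR+BW)")
        if self.combination not in ("CoD", "CoP"):
            raise ConfigError(f"unknown combination {self.combination!r} (CoD, CoP)")
        if self.optimizer not in ("GS", "GA"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r} (GS, GA)")
        if self.reduction == "PR+BW" and self.optimizer == "GS":
            raise ConfigError(
                "PR+BW grid search rejected: the nine-subspace grid is "
                "computationally infeasible; use the GA for the combined reduction"
            )

    @property
    def name(self) -> str:
        return f"{self.reduction}-{self.combination}-{self.optimizer}"

    def plan(self) -> ReductionPlan:
        return ReductionPlan(measures=_REDUCTIONS[self.reduction], lambdas=self.lambdas)


def _dataset_fingerprint(ds: GraphDataset) -> str:
    h = hashlib.sha1()
    for g in ds.graphs:
        h.update(repr((g.graph_id, g.node_labels, g.edges, g.edge_labels)).encode())
        h.update(repr(ds.labels[g.graph_id]).encode())
    return h.hexdigest()[:16]


@dataclass
class GraphEnsembleResults:
    """Fitted ensemble: weights, diagnostics, and the frozen test evaluation."""

    config: ExperimentConfig
    levels: list                       # ordered (measure, lambda) keys
    weights: WeightVector
    alpha: float
    k: int
    level_validation_accuracy: dict    # level -> single-subspace KNN accuracy
    validation_accuracy: float         # combined, at the fitted weights
    test_accuracy: float
    baseline_test_accuracy: float | None
    test_predictions: PredictionVector
    ged_runtimes: dict                 # level -> seconds spent on BP distances
    ga_history: list | None = None

    def weight_table(self):
        import pandas as pd

        rows = [
            {
                "measure": m,
                "lambda": lam,
                "weight": w,
                "validation_accuracy": self.level_validation_accuracy[(m, lam)],
                "ged_seconds": self.ged_runtimes[(m, lam)],
            }
            for (m, lam), w in zip(self.levels, self.weights)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Reduced-subspace ensemble: {self.config.name}",
            "=" * 58,
            f"cost model            alpha={self.alpha:g}  tau_node={self.config.tau_node:g}"
            f"  tau_edge={self.config.tau_edge:g}",
            f"KNN                   k={self.k}",
            f"levels                {len(self.levels)}",
            "",
            f"{'measure':<13}{'lambda':>7}{'weight':>9}{'val acc':>9}{'GED s':>8}",
            "-" * 46,
        ]
        for (m, lam), w in zip(self.levels, self.weights):
            lines.append(
                f"{m:<13}{lam:>7.2f}{w:>9.3f}"
                f"{self.level_validation_accuracy[(m, lam)]:>9.3f}"
                f"{self.ged_runtimes[(m, lam)]:>8.2f}"
            )
        lines += [
            "-" * 46,
            f"combined validation accuracy  {self.validation_accuracy:.4f}",
            f"test accuracy                 {self.test_accuracy:.4f}",
        ]
        if self.baseline_test_accuracy is not None:
            lines.append(f"baseline (original space)     {self.baseline_test_accuracy:.4f}")
        return "\n".join(lines)


class GraphEnsembleClassifier:
    """The three-step ensemble model over centrality-reduced graph subspaces.

    Parameters
    ----------
    data : DatasetSplit or GraphDataset
        A pre-made train/validation/test split, or a dataset to be split
        60/20/20 with the model's seed.
    config : ExperimentConfig
    cache_dir : path, optional
        Directory for on-disk distance-matrix caching, keyed by dataset
        fingerprint, level and cost model (GED dominates the runtime, so
        matrices are reused across optimizer calls and re-runs).
    """

    def __init__(self, data, config: ExperimentConfig = ExperimentConfig(), cache_dir=None):
        if isinstance(data, GraphDataset):
            data = stratified_split(data, (0.6, 0.2, 0.2), seed=config.seed)
        if not isinstance(data, DatasetSplit):
            raise TypeError("data must be a GraphDataset or DatasetSplit")
        self.split = data
        self.config = config
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._matrix_cache: dict = {}

    @classmethod
    def from_dataset(cls, ds: GraphDataset, config: ExperimentConfig = ExperimentConfig(), **kw):
        return cls(ds, config, **kw)

    # -- distance-matrix plumbing ------------------------------------------

    def _cached_matrix(self, key: str, compute) -> DistanceMatrix:
        if key in self._matrix_cache:
            return self._matrix_cache[key]
        if self.cache_dir is not None:
            path = self.cache_dir / f"{key}.tsv"
            if path.exists():
                m = DistanceMatrix.from_tsv(path)
                self._matrix_cache[key] = m
                return m
        m = compute()
        self._matrix_cache[key] = m
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            m.to_tsv(self.cache_dir / f"{key}.tsv")
        return m

    def fit(self, seed: int | None = None) -> GraphEnsembleResults:
        """Run the full pipeline and return the fitted results.

        The weights are optimized against validation accuracy only; the test
        set is evaluated exactly once, at the frozen best weights.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        train, val, test = self.split.train, self.split.validation, self.split.test

        alpha, k = cfg.alpha, cfg.k
        if alpha is None or k is None:
            va, vk = validate_hyperparams(
                train,
                alphas=cfg.alpha_grid,
                ks=cfg.k_grid,
                folds=cfg.cv_folds,
                seed=seed,
                base_cost=CostModel(tau_node=cfg.tau_node, tau_edge=cfg.tau_edge),
            )
            alpha = va if alpha is None else alpha
            k = vk if k is None else k
        cm = CostModel(tau_node=cfg.tau_node, tau_edge=cfg.tau_edge, alpha=alpha)
        knn = KnnConfig(k=k, alpha=alpha)

        plan = cfg.plan()
        stacks = {
            "train": build_subspaces(train, plan),
            "val": build_subspaces(val, plan),
            "test": build_subspaces(test, plan),
        }
        levels = plan.levels()
        fp = "-".join(
            _dataset_fingerprint(d) for d in (train, val, test)
        ) + f"-a{alpha:g}-tn{cfg.tau_node:g}-te{cfg.tau_edge:g}"

        val_mats, test_mats, runtimes = {}, {}, {}
        for lv in levels:
            tag = f"{fp}-{lv[0]}-{lv[1]:g}"
            t0 = time.perf_counter()
            val_mats[lv] = self._cached_matrix(
                f"val-{tag}",
                lambda lv=lv: pairwise_distances(stacks["val"][lv], stacks["train"][lv], cm, lv),
            )
            test_mats[lv] = self._cached_matrix(
                f"test-{tag}",
                lambda lv=lv: pairwise_distances(stacks["test"][lv], stacks["train"][lv], cm, lv),
            )
            runtimes[lv] = time.perf_counter() - t0

        train_labels = dict(train.labels)
        classes = train.classes
        val_truth = dict(val.labels)
        test_truth = dict(test.labels)

        level_val_preds = {lv: knn_predict(train_labels, val_mats[lv], knn) for lv in levels}
        level_val_acc = {lv: accuracy(level_val_preds[lv], val_truth) for lv in levels}

        if cfg.combination == "CoD":
            def evaluate(w: WeightVector) -> float:
                combined = combine_distances([val_mats[lv] for lv in levels], w)
                return accuracy(knn_predict(train_labels, combined, knn), val_truth)
        else:
            pred_list = [level_val_preds[lv] for lv in levels]

            def evaluate(w: WeightVector) -> float:
                return accuracy(combine_predictions(pred_list, w, classes), val_truth)

        history = None
        if cfg.optimizer == "GS":
            best_w, best_f = grid_search(evaluate, GridSpec(len(levels), cfg.grid_values))
        else:
            ga_cfg = replace(cfg.ga, seed=seed)
            best_w, best_f, history = ga_optimize(evaluate, len(levels), ga_cfg)

        if cfg.combination == "CoD":
            combined_test = combine_distances([test_mats[lv] for lv in levels], best_w)
            test_pred = knn_predict(train_labels, combined_test, knn)
        else:
            level_test_preds = [knn_predict(train_labels, test_mats[lv], knn) for lv in levels]
            test_pred = combine_predictions(level_test_preds, best_w, classes)
        test_acc = accuracy(test_pred, test_truth)

        baseline = None
        orig = ("original", 1.0)
        if orig in test_mats:
            baseline = accuracy(knn_predict(train_labels, test_mats[orig], knn), test_truth)

        return GraphEnsembleResults(
            config=cfg,
            levels=levels,
            weights=best_w,
            alpha=alpha,
            k=k,
            level_validation_accuracy=level_val_acc,
            validation_accuracy=float(best_f),
            test_accuracy=float(test_acc),
            baseline_test_accuracy=baseline,
            test_predictions=test_pred,
            ged_runtimes=runtimes,
            ga_history=history,
        )
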