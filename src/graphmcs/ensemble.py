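"""Linear combination of subspace distances or predictions, and the KNN.

Two combination routes condense the per-subspace information into one
classification:

* **CoD** (combination of distances): the meta-distance matrix
  ``D = sum_i w_i D_i`` is fed to a single KNN.
* **CoP** (combination of predictions): each subspace's KNN casts its
  weight for its predicted class and the argmax class wins (weighted
  majority voting).

Both use a weight vector ``w`` on the simplex: entries in [0, 1] summing to
1.  The closed interval is deliberate — corner vectors such as (1, 0, ..., 0)
recover the single-subspace baseline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ged import DistanceMatrix

__all__ = [
    "WeightVector",
    "PredictionVector",
    "KnnConfig",
    "combine_distances",
    "knn_predict",
    "combine_predictions",
    "accuracy",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """Subspace weights on the simplex, aligned with a stack's levels."""

    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0:
            raise ValueError("empty weight vector")
        if np.any(w < -_SIMPLEX_TOL) or np.any(w > 1 + _SIMPLEX_TOL):
            raise ValueError(f"weights outside [0, 1]: {self.weights}")
        if abs(float(w.sum()) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self):
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @classmethod
    def normalized(cls, raw) -> "WeightVector":
        w = np.asarray(raw, dtype=float)
        s = w.sum()
        if s <= 0:
            raise ValueError("cannot normalize a non-positive weight vector")
        return cls(tuple((w / s).tolist()))

    @classmethod
    def unit(cls, i: int, n: int) -> "WeightVector":
        w = [0.0] * n
        w[i] = 1.0
        return cls(tuple(w))


@dataclass(frozen=True)
class PredictionVector:
    """Per-graph class predictions for one subspace (or a combination)."""

    level: tuple
    predictions: dict  # graph_id -> class label

    def ids(self) -> set:
        return set(self.predictions)


@dataclass(frozen=True)
class KnnConfig:
    k: int = 1
    alpha: float = 0.5

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")


def combine_distances(matrices: list, w: WeightVector) -> DistanceMatrix:
    """Meta-distance matrix: the entrywise w-weighted sum of the inputs."""
    if len(matrices) != len(w):
        raise ValueError(f"{len(matrices)} matrices but {len(w)} weights")
    first = matrices[0]
    for m in matrices[1:]:
        if m.row_ids != first.row_ids or m.col_ids != first.col_ids:
            raise ValueError("distance matrices do not share row/col id ordering")
    stacked = np.stack([m.values for m in matrices])
    combined = np.tensordot(w.as_array(), stacked, axes=1)
    return DistanceMatrix(
        row_ids=list(first.row_ids),
        col_ids=list(first.col_ids),
        values=combined,
        level=("combined", float("nan")),
    )


def knn_predict(train_labels: dict, dist_block: DistanceMatrix, cfg: KnnConfig) -> PredictionVector:
    """K-nearest-neighbor classification on a precomputed distance block.

    Rows of ``dist_block`` are evaluation graphs, columns training graphs.
    Per row: majority class among the ``k`` nearest columns.  Distance ties
    resolve by training-set order (stable sort); vote ties by smallest
    summed distance among the tied classes, then by class order.
    """
    missing = [c for c in dist_block.col_ids if c not in train_labels]
    if missing:
        raise ValueError(f"columns without a training label: {missing[:3]}")
    n_train = len(dist_block.col_ids)
    if cfg.k > n_train:
        raise ValueError(f"k={cfg.k} exceeds training-set size {n_train}")
    col_classes = [train_labels[c] for c in dist_block.col_ids]
    class_order = sorted(set(col_classes), key=str)
    preds: dict = {}
    order = np.argsort(dist_block.values, axis=1, kind="stable")
    for i, gid in enumerate(dist_block.row_ids):
        nn = order[i, : cfg.k]
        votes: dict = {}
        sums: dict = {}
        for j in nn:
            cls = col_classes[j]
            votes[cls] = votes.get(cls, 0) + 1
            sums[cls] = sums.get(cls, 0.0) + float(dist_block.values[i, j])
        top = max(votes.values())
        tied = [c for c in class_order if votes.get(c, 0) == top]
        if len(tied) > 1:
            best_sum = min(sums[c] for c in tied)
            tied = [c for c in tied if sums[c] <= best_sum + 1e-12]
        preds[gid] = tied[0]
    return PredictionVector(level=dist_block.level, predictions=preds)


def combine_predictions(preds: list, w: WeightVector, classes: list) -> PredictionVector:
    """Weighted majority voting over per-subspace prediction vectors.

    Each subspace casts its weight for its predicted class; the class with
    the largest total wins, ties broken by the order of ``classes``.
    """
    if len(preds) != len(w):
        raise ValueError(f"{len(preds)} prediction vectors but {len(w)} weights")
    ids = preds[0].ids()
    for p in preds[1:]:
        if p.ids() != ids:
            raise ValueError("prediction vectors do not cover the same evaluation set")
    out: dict = {}
    for gid in preds[0].predictions:
        tally = {c: 0.0 for c in classes}
        for p, wi in zip(preds, w):
            cls = p.predictions[gid]
            if cls not in tally:
                raise ValueError(f"predicted class {cls!r} not in class list")
            tally[cls] += wi
        best = max(tally.values())
        out[gid] = next(c for c in classes if tally[c] >= best - 1e-12)
    return PredictionVector(level=("combined", float("nan")), predictions=out)


def accuracy(pred: PredictionVector, truth: dict) -> float:
    """Fraction of exact label matches over the prediction's coverage."""
    if not pred.ids() <= set(truth):
        raise ValueError("prediction coverage does not match truth labels")
    hits = sum(1 for gid, cls in pred.predictions.items() if truth[gid] == cls)
    return hits / len(pred.predictions)
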