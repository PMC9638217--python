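"""KNN wrapper fitness for feature masks.

A candidate solution is a binary mask over the feature columns.  Its quality is

    fitness = w * alpha + (1 - w) * |s| / |d|

where ``alpha`` is the hold-out classification error of a KNN restricted to
the selected columns, ``|s|`` the number of selected features and ``|d|`` the
total.  Lower is better; ``w`` trades error against subset size.

The KNN here is deliberately hand-rolled and fully deterministic: distance
ties are broken by lower training-row index (stable argsort) and, should a
vote ever tie, by the class of the single nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import LabeledTable, SplitPair

__all__ = [
    "FeatureMask",
    "KnnConfig",
    "ConfusionCounts",
    "FitnessValue",
    "UndefinedMetricError",
    "knn_predict",
    "classification_error",
    "precision_recall",
    "MaskEvaluator",
    "evaluate_mask",
    "exhaustive_oracle",
]


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric has a zero denominator; reported as undefined, not 0."""


@dataclass(frozen=True)
class FeatureMask:
    """Binary selection vector over ``d`` feature columns."""

    bits: tuple

    def __init__(self, bits) -> None:
        arr = np.asarray(bits)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")
        object.__setattr__(self, "bits", tuple(int(b) for b in arr))

    @property
    def d(self) -> int:
        return len(self.bits)

    @property
    def selected_count(self) -> int:
        return int(sum(self.bits))

    @property
    def selected_indices(self) -> list[int]:
        return [j for j, b in enumerate(self.bits) if b]

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)

    @classmethod
    def from_indices(cls, indices, d: int) -> "FeatureMask":
        bits = np.zeros(d, dtype=np.uint8)
        bits[list(indices)] = 1
        return cls(bits)


@dataclass(frozen=True)
class KnnConfig:
    """k nearest neighbours under Euclidean distance; odd k avoids vote ties."""

    k: int = 5
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be an odd positive integer")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean metric is supported")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class FitnessValue:
    """Composite wrapper score plus its components (lower fitness is better)."""

    fitness: float
    error_alpha: float | None
    selected_count: int
    w: float

    def to_dict(self) -> dict:
        return {
            "fitness": self.fitness,
            "error_alpha": self.error_alpha,
            "selected_count": self.selected_count,
            "w": self.w,
        }


def knn_predict(
    train: LabeledTable,
    test_features: np.ndarray,
    mask: FeatureMask,
    cfg: KnnConfig = KnnConfig(),
) -> np.ndarray:
    """Majority vote of the k nearest training rows on the selected columns."""
    sel = mask.selected_indices
    if not sel:
        raise ValueError("mask selects no features")
    if cfg.k > train.n_samples:
        raise ValueError(f"k={cfg.k} exceeds {train.n_samples} training rows")
    A = train.features[:, sel]
    B = np.atleast_2d(np.asarray(test_features, dtype=float))[:, sel]
    # squared Euclidean distances, (n_test, n_train)
    d2 = (
        np.sum(B * B, axis=1)[:, None]
        + np.sum(A * A, axis=1)[None, :]
        - 2.0 * B @ A.T
    )
    # stable sort: equal distances resolve to the lower train-row index
    order = np.argsort(d2, axis=1, kind="stable")[:, : cfg.k]
    votes = train.labels[order]
    pos = votes.sum(axis=1)
    pred = (pos * 2 > cfg.k).astype(int)
    tie = pos * 2 == cfg.k  # only possible if k were even; resolve by 1-NN
    if tie.any():
        pred[tie] = train.labels[order[tie, 0]]
    return pred


def classification_error(predictions, labels) -> tuple[float, ConfusionCounts]:
    """Error rate alpha = 1 - accuracy plus the confusion counts (positive = 1)."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape or p.size == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    counts = ConfusionCounts(
        TP=int(np.sum((p == 1) & (y == 1))),
        TN=int(np.sum((p == 0) & (y == 0))),
        FP=int(np.sum((p == 1) & (y == 0))),
        FN=int(np.sum((p == 0) & (y == 1))),
    )
    alpha = (counts.FP + counts.FN) / counts.total
    return alpha, counts


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); zero denominators raise."""
    if counts.TP + counts.FP == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("recall undefined: no positive labels")
    return counts.TP / (counts.TP + counts.FP), counts.TP / (counts.TP + counts.FN)


class MaskEvaluator:
    """Memoized wrapper-fitness evaluator bound to one split/config/weight.

    ``n_evaluations`` counts distinct KNN fits (cache misses); ``n_calls``
    counts every request.  The empty mask is defined as worst fitness 1.0 with
    an undefined error.
    """

    def __init__(self, split: SplitPair, cfg: KnnConfig = KnnConfig(), w: float = 0.2):
        if not 0.0 <= w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if set(split.train.labels) != {0, 1}:
            raise ValueError("training part must contain both classes")
        self.split = split
        self.cfg = cfg
        self.w = w
        self._cache: dict[tuple, FitnessValue] = {}
        self.n_evaluations = 0
        self.n_calls = 0

    @property
    def d(self) -> int:
        return self.split.train.n_features

    def __call__(self, mask: FeatureMask) -> FitnessValue:
        self.n_calls += 1
        key = mask.bits
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if mask.selected_count == 0:
            fv = FitnessValue(1.0, None, 0, self.w)
        else:
            pred = knn_predict(self.split.train, self.split.test.features, mask, self.cfg)
            alpha, _ = classification_error(pred, self.split.test.labels)
            fit = self.w * alpha + (1.0 - self.w) * mask.selected_count / self.d
            fv = FitnessValue(fit, alpha, mask.selected_count, self.w)
            self.n_evaluations += 1
        self._cache[key] = fv
        return fv


def evaluate_mask(
    mask: FeatureMask,
    split: SplitPair,
    cfg: KnnConfig = KnnConfig(),
    w: float = 0.2,
) -> FitnessValue:
    """One-off fitness of ``mask`` on ``split`` (see :class:`MaskEvaluator`)."""
    return MaskEvaluator(split, cfg, w)(mask)


def _mask_sort_key(mask: FeatureMask, fit: FitnessValue) -> tuple:
    return (fit.fitness, mask.selected_count, mask.bits)


def exhaustive_oracle(
    split: SplitPair,
    cfg: KnnConfig = KnnConfig(),
    w: float = 0.2,
    max_d: int = 16,
) -> tuple[FeatureMask, FitnessValue]:
    """Global minimum of the wrapper fitness over all 2^d - 1 non-empty masks.

    Brute force; refuses d > ``max_d``.  Ties break toward fewer selected
    features, then the lexicographically smallest bit tuple.
    """
    d = split.train.n_features
    if d > max_d:
        raise ValueError(f"d={d} too large for exhaustive enumeration (max {max_d})")
    ev = MaskEvaluator(split, cfg, w)
    best: tuple | None = None
    for code in range(1, 2**d):
        bits = [(code >> j) & 1 for j in range(d)]
        mask = FeatureMask(bits)
        fit = ev(mask)
        key = _mask_sort_key(mask, fit)
        if best is None or key < best[0]:
            best = (key, mask, fit)
    assert best is not None
    return best[1], best[2]
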