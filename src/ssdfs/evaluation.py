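"""Experiment protocol: repeated runs with mean ± SD reporting, Mann-Whitney U
comparison between methods, and ground-truth recovery scoring on synthetic data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .fitness import (
    UndefinedMetricError,
    classification_error,
    knn_predict,
    precision_recall,
)
from .ssd import SSDConfig, SelectionResult, run_ssd, _prepare_split
from .synthetic import GroundTruth

__all__ = [
    "RunMetrics",
    "ExperimentReport",
    "RecoveryScore",
    "mean_sd",
    "repeat_experiment",
    "mann_whitney_u",
    "score_recovery",
]


@dataclass(frozen=True)
class RunMetrics:
    accuracy_pct: float
    precision_pct: float
    recall_pct: float
    selected_count: int
    fitness: float
    seed: int


def mean_sd(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass
class ExperimentReport:
    """Per-run metrics over repeated simulations plus their mean ± sample SD."""

    per_run: list[RunMetrics]
    seeds: list[int]
    results: list[SelectionResult]

    def column(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.per_run]

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: mean_sd(self.column(name))
            for name in ("accuracy_pct", "precision_pct", "recall_pct", "selected_count")
        }

    def to_markdown(self) -> str:
        lines = [
            "| Simulation | Accuracy (%) | Precision (%) | Recall (%) | #FS |",
            "|---|---|---|---|---|",
        ]
        for i, r in enumerate(self.per_run, start=1):
            lines.append(
                f"| {i} | {r.accuracy_pct:.2f} | {r.precision_pct:.2f} "
                f"| {r.recall_pct:.2f} | {r.selected_count} |"
            )
        s = self.summary()
        lines.append(
            "| Mean ± SD | {0[0]:.2f} ± {0[1]:.2f} | {1[0]:.2f} ± {1[1]:.2f} "
            "| {2[0]:.2f} ± {2[1]:.2f} | {3[0]:.0f} ± {3[1]:.0f} |".format(
                s["accuracy_pct"], s["precision_pct"], s["recall_pct"],
                s["selected_count"],
            )
        )
        return "\n".join(lines)


def repeat_experiment(
    table_or_split,
    cfg: SSDConfig,
    n_runs: int = 5,
    base_seed: int = 0,
) -> ExperimentReport:
    """Run the optimizer ``n_runs`` times (seeds base_seed..base_seed+n-1) on a
    single fixed split and score each run's best mask on the held-out part.

    Final metrics refit the KNN with the selected columns on the training part
    and score the test part; precision/recall that are undefined for a run
    (no positive predictions) are reported as NaN.
    """
    if n_runs < 2:
        raise ValueError("need >= 2 runs for a mean ± SD report")
    split = _prepare_split(table_or_split, cfg)
    per_run: list[RunMetrics] = []
    results: list[SelectionResult] = []
    seeds = [base_seed + i for i in range(n_runs)]
    for seed in seeds:
        res = run_ssd(split, replace(cfg, seed=seed))
        pred = knn_predict(split.train, split.test.features, res.best_mask, cfg.knn)
        alpha, counts = classification_error(pred, split.test.labels)
        try:
            prec, rec = precision_recall(counts)
        except UndefinedMetricError:
            prec = rec = float("nan")
        per_run.append(
            RunMetrics(
                accuracy_pct=100.0 * (1.0 - alpha),
                precision_pct=100.0 * prec,
                recall_pct=100.0 * rec,
                selected_count=res.best_mask.selected_count,
                fitness=res.best_fitness.fitness,
                seed=seed,
            )
        )
        results.append(res)
    return ExperimentReport(per_run, seeds, results)


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(xs, ys, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Returns ``(U, p)`` where U is the statistic of ``xs``.  For n1+n2 <= 12 the
    p-value is exact, by enumerating all C(n1+n2, n1) rank assignments under
    the null (ties handled through midranks); larger samples use the
    tie-corrected normal approximation (scipy, with continuity correction).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    n1, n2 = xs.size, ys.size
    ranks = stats.rankdata(np.concatenate([xs, ys]))
    U = _u_statistic(ranks[:n1], n1)

    if n1 + n2 <= 12:
        mu = n1 * n2 / 2.0
        dev = abs(U - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(combo)], n1)
            total += 1
            if alternative == "two-sided":
                hits += abs(u - mu) >= dev - 1e-12
            elif alternative == "less":
                hits += u <= U + 1e-12
            elif alternative == "greater":
                hits += u >= U - 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return U, hits / total

    res = stats.mannwhitneyu(xs, ys, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RecoveryScore:
    """How well a selection recovered the generator's ground truth.

    ``informative_recall`` counts an informative source as recovered if the
    source itself or any of its redundant copies is selected;
    ``noise_fraction`` is the share of selected features that are pure noise.
    """

    informative_recall: float
    noise_fraction: float


def score_recovery(result: SelectionResult, truth: GroundTruth) -> RecoveryScore:
    selected = set(result.selected_indices)
    informative = set(truth.informative_indices)
    noise = set(truth.noise_indices)
    d = len(informative) + len(truth.redundant_map) + len(noise)
    if result.best_mask.d != d:
        raise ValueError("mask dimension does not match ground truth")
    recovered = set(selected & informative)
    for red, src in truth.redundant_map.items():
        if red in selected:
            recovered.add(src)
    recall = len(recovered) / len(informative)
    noise_frac = len(selected & noise) / len(selected) if selected else 0.0
    return RecoveryScore(recall, noise_frac)
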