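"""Binary Social Ski-Driver (SSD) optimizer for wrapper feature selection.

Agents carry a binary location (a feature mask) and a real velocity.  Each
iteration every agent is pulled toward its personal best and toward the mean
of the three best solutions found so far (MGB) through sine/cosine-weighted
steps scaled by an exploration weight h that decays geometrically (h <- r*h).
The real velocity is mapped to per-bit flip probabilities by the V-shaped
transfer function |x|/sqrt(1+x^2), and every agent is refined each iteration
by ABHC local search.  Bookkeeping is elitist: the global best never worsens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .abhc import ABHCConfig, abhc_refine
from .fitness import FeatureMask, FitnessValue, KnnConfig, MaskEvaluator
from .tabular import LabeledTable, SplitPair, standardize, stratified_split

__all__ = [
    "Agent",
    "SSDConfig",
    "SelectionResult",
    "v_transfer",
    "decay_h",
    "mean_global_best",
    "update_velocity",
    "binarize_step",
    "run_ssd",
]


def v_transfer(x):
    """V-shaped transfer |x|/sqrt(1+x^2): even, increasing in |x|, in [0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.abs(x) / np.sqrt(1.0 + x * x)
    return float(out) if out.ndim == 0 else out


def decay_h(h: float, r: float) -> float:
    """Geometric decay of the exploration weight: h -> r*h."""
    if h <= 0 or not 0 < r <= 1:
        raise ValueError("need h > 0 and 0 < r <= 1")
    return r * h


def mean_global_best(top3_masks) -> np.ndarray:
    """Elementwise mean of the top-3 locations (bits treated as reals)."""
    arrs = [np.asarray(m.as_array() if isinstance(m, FeatureMask) else m, dtype=float)
            for m in top3_masks]
    if len(arrs) != 3:
        raise ValueError("exactly three locations required")
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("locations must have equal length")
    return (arrs[0] + arrs[1] + arrs[2]) / 3.0


@dataclass
class Agent:
    """One ski driver: binary location, real velocity, and its personal best."""

    location: FeatureMask
    velocity: np.ndarray
    personal_best_mask: FeatureMask
    personal_best_fitness: FitnessValue
    rng: np.random.Generator


def update_velocity(
    agent: Agent, mgb: np.ndarray, h: float, rng: np.random.Generator
) -> np.ndarray:
    """Sine- or cosine-weighted attraction toward PB and MGB (no inertia term).

    One uniform draw picks the branch (sine if <= 0.5); each attraction term
    then gets a fresh uniform draw per dimension inside sin/cos.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    loc = agent.location.as_array().astype(float)
    pb = agent.personal_best_mask.as_array().astype(float)
    d = loc.size
    f = np.sin if rng.random() <= 0.5 else np.cos
    v = h * f(rng.random(d)) * (pb - loc) + f(rng.random(d)) * (mgb - loc)
    if not np.isfinite(v).all():
        raise FloatingPointError("non-finite velocity")
    return v


def binarize_step(
    current: FeatureMask, velocity: np.ndarray, rng: np.random.Generator
) -> FeatureMask:
    """Flip bit j with probability V(velocity_j); repair an all-zero result."""
    bits = current.as_array()
    if velocity.shape != (current.d,):
        raise ValueError("velocity length must match mask length")
    flip = v_transfer(velocity) > rng.random(current.d)
    new_bits = np.where(flip, 1 - bits, bits).astype(np.uint8)
    if not new_bits.any():
        new_bits[rng.integers(current.d)] = 1
    return FeatureMask(new_bits)


@dataclass(frozen=True)
class SSDConfig:
    """Full optimizer configuration (defaults follow the study's settings:
    population 20, 100 iterations, h0=100, r=0.9, w=0.2)."""

    population_size: int = 20
    max_iterations: int = 100
    h0: float = 100.0
    r: float = 0.9
    w: float = 0.2
    knn: KnnConfig = field(default_factory=KnnConfig)
    abhc: ABHCConfig = field(default_factory=ABHCConfig)
    seed: int = 0
    test_fraction: float = 0.2
    split_seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 3:
            raise ValueError("population_size must be >= 3 (top-3 attractor)")
        if not 0 < self.r < 1:
            raise ValueError("r must be in (0, 1)")
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "max_iterations": self.max_iterations,
            "h0": self.h0,
            "r": self.r,
            "w": self.w,
            "knn": {"k": self.knn.k, "distance": self.knn.distance},
            "abhc": {"MT": self.abhc.MT, "c": self.abhc.c,
                     "Mi": self.abhc.Mi, "Ma": self.abhc.Ma},
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "split_seed": self.split_seed,
            "standardize": self.standardize,
        }


@dataclass
class SelectionResult:
    """Outcome of one optimizer run."""

    best_mask: FeatureMask
    best_fitness: FitnessValue
    selected_indices: list[int]
    fitness_history: list[float]
    n_evaluations: int
    seed: int

    def to_json(self, path=None) -> str:
        obj = {
            "best_mask": list(self.best_mask.bits),
            "best_fitness": self.best_fitness.to_dict(),
            "selected_indices": self.selected_indices,
            "fitness_history": self.fitness_history,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class _Top3Archive:
    """The three best distinct masks found so far; ties favour smaller masks,
    then the lexicographically smallest bit tuple."""

    def __init__(self) -> None:
        self._entries: dict[tuple, FitnessValue] = {}

    def update(self, mask: FeatureMask, fit: FitnessValue) -> None:
        self._entries.setdefault(mask.bits, fit)

    def top3(self) -> list[tuple[FeatureMask, FitnessValue]]:
        ranked = sorted(
            self._entries.items(),
            key=lambda kv: (kv[1].fitness, sum(kv[0]), kv[0]),
        )
        best = [(FeatureMask(bits), fit) for bits, fit in ranked[:3]]
        while len(best) < 3:  # early, before 3 distinct masks exist
            best.append(best[0])
        return best

    @property
    def best(self) -> tuple[FeatureMask, FitnessValue]:
        return self.top3()[0]


def _prepare_split(table_or_split, cfg: SSDConfig) -> SplitPair:
    if isinstance(table_or_split, SplitPair):
        return table_or_split
    table: LabeledTable = table_or_split
    if min(table.class_counts()) < 2:
        raise ValueError("table must contain >= 2 samples of each class")
    split = stratified_split(table, cfg.test_fraction, cfg.split_seed)
    if cfg.standardize:
        split = standardize(split.train, split.test)
    return split


def _random_mask(d: int, rng: np.random.Generator) -> FeatureMask:
    bits = (rng.random(d) < 0.5).astype(np.uint8)
    if not bits.any():
        bits[rng.integers(d)] = 1
    return FeatureMask(bits)


def run_ssd(table_or_split, cfg: SSDConfig = SSDConfig()) -> SelectionResult:
    """Run the ABHC-embedded binary SSD and return the best mask found.

    Accepts either a :class:`LabeledTable` (split and standardized internally
    with ``cfg.split_seed``/``cfg.test_fraction``) or a ready
    :class:`SplitPair` (used as-is, e.g. to share a split with the exhaustive
    oracle).  The master seed spawns one independent RNG stream per agent, so
    results are bit-identical across replays of the same configuration.
    """
    split = _prepare_split(table_or_split, cfg)
    evaluator = MaskEvaluator(split, cfg.knn, cfg.w)
    d = evaluator.d

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.population_size)
    archive = _Top3Archive()
    agents: list[Agent] = []
    for child in streams:
        rng = np.random.default_rng(child)
        mask = _random_mask(d, rng)
        fit = evaluator(mask)
        agents.append(Agent(mask, np.zeros(d), mask, fit, rng))
        archive.update(mask, fit)

    history = [archive.best[1].fitness]
    h = cfg.h0
    for _ in range(cfg.max_iterations):
        mgb = mean_global_best([m for m, _ in archive.top3()])
        for agent in agents:
            agent.velocity = update_velocity(agent, mgb, h, agent.rng)
            moved = binarize_step(agent.location, agent.velocity, agent.rng)
            moved_fit = evaluator(moved)
            archive.update(moved, moved_fit)
            refined, refined_fit, _ = abhc_refine(
                moved, evaluator, cfg.abhc, agent.rng
            )
            agent.location = refined
            archive.update(refined, refined_fit)
            if refined_fit.fitness < agent.personal_best_fitness.fitness:
                agent.personal_best_mask = refined
                agent.personal_best_fitness = refined_fit
        h = decay_h(h, cfg.r)
        history.append(archive.best[1].fitness)

    best_mask, best_fit = archive.best
    assert all(b >= a for a, b in zip(history[1:], history)), "history must not increase"
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        selected_indices=best_mask.selected_indices,
        fitness_history=history,
        n_evaluations=evaluator.n_evaluations,
        seed=cfg.seed,
    )
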