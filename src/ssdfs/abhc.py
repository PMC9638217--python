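"""Adaptive Beta Hill Climbing (ABHC) refinement of a single feature mask.

A shrinking neighbourhood radius N(z) perturbs the mask in a relaxed [0,1]
representation, a growing mutation probability Beta(z) mixes the perturbed
coordinates back with the incumbent, the result is clipped and thresholded to
bits, and a proposal replaces the incumbent only on a strict fitness
improvement.  With a finite budget MT this terminates and never worsens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fitness import FeatureMask, FitnessValue

__all__ = [
    "ABHCConfig",
    "LocalSearchTrace",
    "neighborhood_radius",
    "beta_schedule",
    "neighbor_move",
    "beta_mutation",
    "abhc_refine",
]


@dataclass(frozen=True)
class ABHCConfig:
    """Local-search budget and schedule shape.

    MT  -- proposals per refinement call (fitness evaluations used).
    c   -- curvature of the radius decay; c=1 is linear.
    Mi, Ma -- Beta's start/end values: the probability of keeping an
    incumbent coordinate grows from Mi to Ma over the MT proposals.
    """

    MT: int = 10
    c: float = 2.0
    Mi: float = 0.01
    Ma: float = 0.5

    def __post_init__(self) -> None:
        if self.MT < 1:
            raise ValueError("MT must be >= 1")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if not 0.0 <= self.Mi <= self.Ma <= 1.0:
            raise ValueError("need 0 <= Mi <= Ma <= 1")


@dataclass
class LocalSearchTrace:
    start_fitness: float
    end_fitness: float
    accepted_moves: int
    evaluations: int


def neighborhood_radius(z: int, MT: int, c: float) -> float:
    """N(z) = 1 - z^(1/c) / MT^(1/c): from 1 at z=0 down to 0 at z=MT."""
    if not 0 <= z <= MT:
        raise ValueError(f"iteration z={z} outside [0, {MT}]")
    return 1.0 - (z ** (1.0 / c)) / (MT ** (1.0 / c))


def beta_schedule(z: int, MT: int, Mi: float, Ma: float) -> float:
    """Beta(z) = (Ma - Mi) * z / MT + Mi: linear ramp from Mi to Ma."""
    if not 0 <= z <= MT:
        raise ValueError(f"iteration z={z} outside [0, {MT}]")
    return (Ma - Mi) * z / MT + Mi


def neighbor_move(L: FeatureMask, N: float, rng: np.random.Generator) -> np.ndarray:
    """Relaxed neighbour L'_j = L_j ± rand_j(0,1) * N, sign by fair coin per j."""
    bits = L.as_array().astype(float)
    signs = np.where(rng.random(L.d) < 0.5, 1.0, -1.0)
    return bits + signs * rng.random(L.d) * N


def beta_mutation(
    L: FeatureMask,
    L_prime: np.ndarray,
    Beta: float,
    rng: np.random.Generator,
) -> FeatureMask:
    """Keep L_j where Beta > rand_j, else take L'_j; clip to [0,1], threshold 0.5.

    Ties at exactly 0.5 binarize to 1.  An all-zero outcome is repaired by
    switching one uniformly chosen bit on.
    """
    if not 0.0 <= Beta <= 1.0:
        raise ValueError("Beta must lie in [0, 1]")
    bits = L.as_array().astype(float)
    keep = Beta > rng.random(L.d)
    mixed = np.where(keep, bits, np.asarray(L_prime, dtype=float))
    mixed = np.clip(mixed, 0.0, 1.0)
    new_bits = (mixed >= 0.5).astype(np.uint8)
    if not new_bits.any():
        new_bits[rng.integers(L.d)] = 1
    return FeatureMask(new_bits)


def abhc_refine(
    mask: FeatureMask,
    evaluator: Callable[[FeatureMask], FitnessValue],
    cfg: ABHCConfig = ABHCConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMask, FitnessValue, LocalSearchTrace]:
    """Run MT strict-improvement proposals from ``mask``; never returns worse.

    ``evaluator`` is any mask -> fitness callable (typically a memoized
    :class:`~ssdfs.fitness.MaskEvaluator`, so re-scoring the start mask is
    free).  Exactly ``cfg.MT`` proposal evaluations are made.
    """
    if mask.selected_count == 0:
        raise ValueError("cannot refine an empty mask")
    if rng is None:
        rng = np.random.default_rng()
    current, cur_fit = mask, evaluator(mask)
    start = cur_fit.fitness
    accepted = 0
    for z in range(1, cfg.MT + 1):
        N = neighborhood_radius(z, cfg.MT, cfg.c)
        Beta = beta_schedule(z, cfg.MT, cfg.Mi, cfg.Ma)
        proposal = beta_mutation(current, neighbor_move(current, N, rng), Beta, rng)
        prop_fit = evaluator(proposal)
        if prop_fit.fitness < cur_fit.fitness:
            current, cur_fit = proposal, prop_fit
            accepted += 1
    trace = LocalSearchTrace(start, cur_fit.fitness, accepted, cfg.MT)
    return current, cur_fit, trace
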