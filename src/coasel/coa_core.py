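"""The coati optimization loop for binary feature selection.

A population of N binary masks ("coatis") is evolved for up to T
iterations. Each iteration: the lowest-fitness coati becomes the leader
(dominant male); every other coati probabilistically adopts bits from
the leader via the switching probability ``S = r1 * (1 - r2 * x)``
(territorial movement), then its bitwise complement is evaluated and
kept if strictly better (opposition-based learning); finally the leader
is re-selected. The leader itself is never moved or opposed, so the
best-so-far solution survives every iteration (elitism) and the
best-fitness trace is non-increasing.

No user-tuned movement coefficients exist beyond N, T and the
initialization probability p: the switching probabilities are drawn
fresh per bit, which is the parameter-free adaptation of the method.

Randomness comes from one seeded generator with a documented draw
order — initialization bits row-major (coati outer, bit inner); then,
per iteration, movement draws ``r1, r2, u`` per bit in coati order —
so identical seeds yield bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .encoding import BinaryMask, FeatureMatrix, opposite
from .fitness import ClassifierAdapter, FitnessCache, FitnessValue, fitness

__all__ = [
    "COAConfig",
    "COAResult",
    "initialize_population",
    "select_leader",
    "switching_probability",
    "territorial_move",
    "opposition_step",
    "run_coa",
]


@dataclass(frozen=True)
class COAConfig:
    """Run parameters for the coati search.

    N : population size (default 20)
    T : maximum iterations (default 50)
    p : per-bit probability of a 1 at initialization (default 0.5)
    seed : RNG seed; identical seeds give bit-identical results
    early_stop_eps / early_stop_window : stop once the best fitness has
        improved by less than ``eps`` over the last ``window`` iterations
    """

    N: int = 20
    T: int = 50
    p: float = 0.5
    seed: int = 0
    early_stop_eps: float = 1e-6
    early_stop_window: int = 10

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.T < 1:
            raise ValueError("max iterations T must be >= 1")
        if not 0.0 < self.p < 1.0:
            raise ValueError("initialization probability p must be in (0, 1)")
        if self.early_stop_eps < 0:
            raise ValueError("early_stop_eps must be >= 0")
        if self.early_stop_window < 1:
            raise ValueError("early_stop_window must be >= 1")


@dataclass
class COAResult:
    """Outcome of a coati run: best mask, its fitness, and diagnostics."""

    best_mask: BinaryMask
    best_fitness: FitnessValue
    trace: List[float]
    n_evaluations: int
    seed: int
    n_iterations: int = 0
    stopped_early: bool = False


def initialize_population(cfg: COAConfig, d: int,
                          rng: np.random.Generator) -> List[BinaryMask]:
    """Draw N masks; each bit is 1 iff its uniform draw is below p.

    Draws are consumed row-major: coati index outer, bit index inner.
    """
    if d < 1:
        raise ValueError("feature dimension d must be >= 1")
    draws = rng.random((cfg.N, d))
    return [BinaryMask(tuple(int(u < cfg.p) for u in row)) for row in draws]


def select_leader(fitnesses: Sequence[FitnessValue]) -> int:
    """Index of the minimum-fitness coati; ties go to the lowest index."""
    if len(fitnesses) == 0:
        raise ValueError("cannot select a leader from an empty population")
    values = [fv.value for fv in fitnesses]
    return int(np.argmin(values))


def switching_probability(bit: int, r1: float, r2: float) -> float:
    """Per-bit adoption probability ``S = r1 * (1 - r2 * bit)``.

    For a 0 bit this reduces to r1; a 1 bit is stickier, shrinking the
    chance it is overwritten by the leader's bit.
    """
    return r1 * (1.0 - r2 * bit)


def territorial_move(coati: BinaryMask, leader: BinaryMask,
                     rng: np.random.Generator) -> BinaryMask:
    """Per bit: draw r1, r2, u; adopt the leader's bit iff ``u < S``."""
    if coati.d != leader.d:
        raise ValueError("coati and leader masks must have equal length")
    new_bits = []
    for x, x_star in zip(coati.bits, leader.bits):
        r1 = rng.random()
        r2 = rng.random()
        u = rng.random()
        s = switching_probability(x, r1, r2)
        new_bits.append(x_star if u < s else x)
    return BinaryMask(tuple(new_bits))


def opposition_step(coati: BinaryMask, fv: FitnessValue,
                    evaluator) -> tuple:
    """Evaluate the complement mask; keep it iff strictly lower fitness."""
    opp = opposite(coati)
    opp_fv = evaluator(opp)
    if opp_fv.value < fv.value:
        return opp, opp_fv
    return coati, fv


def run_coa(F: FeatureMatrix, cfg: Optional[COAConfig] = None,
            clf: Optional[ClassifierAdapter] = None,
            callback=None) -> COAResult:
    """Run the full coati search on a feature matrix.

    ``callback(iteration, best_fitness, n_distinct_masks)``, when given,
    is invoked once per completed iteration (for logging).
    """
    cfg = cfg if cfg is not None else COAConfig()
    rng = np.random.default_rng(cfg.seed)
    cache = FitnessCache()

    def evaluate(mask: BinaryMask) -> FitnessValue:
        return fitness(F, mask, clf, cache)

    population = initialize_population(cfg, F.d, rng)
    fitnesses = [evaluate(m) for m in population]

    leader_idx = select_leader(fitnesses)
    trace = [fitnesses[leader_idx].value]

    n_iterations = 0
    stopped_early = False
    for t in range(1, cfg.T + 1):
        leader = population[leader_idx]
        for i in range(cfg.N):
            if i == leader_idx:
                continue  # the leader is exempt: elitism
            moved = territorial_move(population[i], leader, rng)
            moved_fv = evaluate(moved)
            population[i], fitnesses[i] = opposition_step(moved, moved_fv,
                                                          evaluate)
        leader_idx = select_leader(fitnesses)
        trace.append(fitnesses[leader_idx].value)
        n_iterations = t
        if callback is not None:
            callback(t, trace[-1], len(cache))
        w = cfg.early_stop_window
        if t >= w and trace[-1 - w] - trace[-1] < cfg.early_stop_eps:
            stopped_early = t < cfg.T
            break

    return COAResult(best_mask=population[leader_idx],
                     best_fitness=fitnesses[leader_idx],
                     trace=trace,
                     n_evaluations=len(cache),
                     seed=cfg.seed,
                     n_iterations=n_iterations,
                     stopped_early=stopped_early)
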