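"""Generic binary-vector genetic algorithm with "doping".

Both evolutionary searches of the protocol — the representative
train/test-split search and the feature-mask search — optimize a fixed-
length bit vector, so they share this engine.  Premature convergence is
countered two ways, operationalizing genetic doping: a fraction of every
generation is replaced by fresh random immigrants, and tournament selection
occasionally lets the *loser* through, retaining sub-optimal parents.
Elitism guarantees the best-ever fitness trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class GAConfig:
    """Evolution parameters.

    ``mutation_rate=None`` means the customary 1/L per bit.  Defaults
    follow the protocol's published run lengths: population 100 evolved
    for 500 generations, crossover 0.9, 10% immigrants, 2 elites.
    """

    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    immigrant_fraction: float = 0.1
    elitism: int = 2
    tournament_size: int = 2
    loser_win_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        for name in ("crossover_rate", "immigrant_fraction", "loser_win_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class GAResult:
    best: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-ever fitness after each generation; non-decreasing


def evolve(
    fitness: Callable[[np.ndarray], float],
    n_bits: int,
    config: GAConfig,
    repair: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    init: Callable[[np.random.Generator], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Maximize ``fitness`` over bit vectors of length ``n_bits``.

    ``repair`` coerces candidates back into the feasible set (e.g. at
    least one bit set); it must be deterministic given the generator.
    Fitness values are cached by genome so elites are never re-scored.
    """
    rng = rng or np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_bits
    pop_n = config.population_size
    n_imm = int(np.ceil(config.immigrant_fraction * pop_n)) if config.immigrant_fraction > 0 else 0
    n_elite = min(config.elitism, pop_n)

    def fresh() -> np.ndarray:
        bits = init(rng) if init is not None else rng.integers(0, 2, size=n_bits).astype(np.int8)
        return repair(bits, rng) if repair is not None else bits

    cache: dict[bytes, float] = {}

    def score(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = float(fitness(bits))
        return cache[key]

    pop = [fresh() for _ in range(pop_n)]
    fits = np.array([score(b) for b in pop])
    best_i = int(np.argmax(fits))
    best, best_fit = pop[best_i].copy(), fits[best_i]
    trace = []

    def pick_parent() -> np.ndarray:
        idx = rng.integers(0, pop_n, size=config.tournament_size)
        order = idx[np.argsort(fits[idx], kind="stable")]
        # doping: with small probability the tournament loser reproduces
        if len(order) > 1 and rng.random() < config.loser_win_prob:
            return pop[order[0]]
        return pop[order[-1]]

    for _ in range(config.generations):
        elite_order = np.argsort(fits, kind="stable")[::-1][:n_elite]
        nxt = [pop[i].copy() for i in elite_order]
        while len(nxt) < pop_n - n_imm:
            p1 = pick_parent()
            if rng.random() < config.crossover_rate:
                p2 = pick_parent()
                mask = rng.integers(0, 2, size=n_bits).astype(bool)
                child = np.where(mask, p1, p2).astype(np.int8)
            else:
                child = p1.copy()
            if mut > 0:
                flips = rng.random(n_bits) < mut
                child = np.where(flips, 1 - child, child).astype(np.int8)
            if repair is not None:
                child = repair(child, rng)
            nxt.append(child)
        while len(nxt) < pop_n:
            nxt.append(fresh())
        pop = nxt
        fits = np.array([score(b) for b in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), fits[gen_best]
        trace.append(best_fit)

    return GAResult(best=best, best_fitness=float(best_fit), trace=np.array(trace))
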