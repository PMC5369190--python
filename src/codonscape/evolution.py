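"""Genetic algorithm over hypothetical genetic codes.

The GA minimizes the error cost of :mod:`codonscape.error_cost` over either
code model.  Each generation: (1) if fitness sharing is active, the pairwise
distance matrix and shared costs are computed; (2) offspring are produced by
tournament selection (window sampled without replacement, best selection
cost wins, ties to the lowest index); (3) each offspring undergoes at most
one swap of two positions with probability ``swap_prob`` and — for the
unrestrictive model only — per-position mutation with probability
``mutation_prob``; (4) the elite parent is copied unchanged over the worst
offspring by raw cost; (5) per-generation statistics are taken from raw
costs.  Crossover is deliberately absent: it cannot guarantee that every
offspring still encodes all 20 amino acids, whereas swap and mutation
preserve that invariant by construction.

Populations are held as stacked integer arrays — (N, 20) permutations for
the restrictive model, (N, 64) label arrays for the unrestrictive one — so
that cost and distance evaluations vectorize over the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import code_model as cm
from . import error_cost as ec
from . import niching

__all__ = [
    "GAConfig",
    "GenerationStats",
    "RunRecord",
    "Aggregate",
    "swap_operator",
    "mutation_operator",
    "tournament_select",
    "step",
    "run",
    "multi_run",
]


@dataclass(frozen=True)
class GAConfig:
    """All evolutionary, sharing and reproducibility parameters.

    Defaults mirror the study conditions: population 1000, 100 generations,
    swap probability 0.5 per offspring, per-position mutation probability
    0.01 (unrestrictive model only), tournament window 3% of the population,
    elitism on.  ``elitism_cost`` selects which cost crowns the elite:
    ``"selection"`` (the cost actually used for selection, i.e. the shared
    cost when sharing is active) or ``"raw"``.  ``mutation_per_position``
    switches the 0.01 to a per-individual reading when False.
    """

    model: str = "restrictive"
    scheme: str = "ms"
    population_size: int = 1000
    generations: int = 100
    mutation_prob: float = 0.01
    swap_prob: float = 0.5
    tournament_fraction: float = 0.03
    sharing: niching.SharingConfig | None = None
    elitism: bool = True
    elitism_cost: str = "selection"
    mutation_per_position: bool = True
    seed_canonical: bool = False
    rng_seed: int = 0
    n_runs: int = 10

    def __post_init__(self) -> None:
        if self.model not in ("restrictive", "unrestrictive"):
            raise ValueError(f"unknown model {self.model!r}")
        for p in (self.mutation_prob, self.swap_prob, self.tournament_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tournament_window < 1:
            raise ValueError("tournament window must be >= 1")
        if self.elitism_cost not in ("selection", "raw"):
            raise ValueError("elitism_cost must be 'selection' or 'raw'")

    @property
    def tournament_window(self) -> int:
        return max(1, round(self.tournament_fraction * self.population_size))

    @property
    def genotype_length(self) -> int:
        return 20 if self.model == "restrictive" else 64


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best_cost: float
    mean_cost: float
    canonical_present: bool


@dataclass(frozen=True)
class RunRecord:
    """Everything the landscape analyses need from one GA run."""

    config: GAConfig
    stats: tuple[GenerationStats, ...]
    final_population: np.ndarray
    final_costs: np.ndarray
    best_genotype: cm.RestrictiveGenotype | cm.UnrestrictiveGenotype
    best_cost: float  # best raw cost seen at any generation

    @property
    def final_best(self) -> float:
        return self.stats[-1].best_cost

    @property
    def final_mean(self) -> float:
        return self.stats[-1].mean_cost


@dataclass(frozen=True)
class Aggregate:
    """Ensemble means and standard deviations of final-generation statistics."""

    n_runs: int
    best_mean: float
    best_sd: float
    average_mean: float
    average_sd: float


def _canonical_row(model: str) -> np.ndarray:
    return np.arange(20) if model == "restrictive" else cm.canonical_assignment()


def _wrap_genotype(row: np.ndarray, model: str):
    if model == "restrictive":
        return cm.RestrictiveGenotype(perm=row.copy())
    return cm.UnrestrictiveGenotype(assign=row.copy())


def _raw_costs(pop: np.ndarray, cfg: GAConfig) -> np.ndarray:
    if cfg.model == "restrictive":
        return ec.permutation_costs(pop, weights=cfg.scheme)
    return ec.assignment_costs(pop, weights=cfg.scheme)


def swap_operator(genotype, rng: np.random.Generator):
    """Exchange the contents of two distinct random positions."""
    if isinstance(genotype, cm.RestrictiveGenotype):
        arr, wrap = genotype.perm.copy(), cm.RestrictiveGenotype
    elif isinstance(genotype, cm.UnrestrictiveGenotype):
        arr, wrap = genotype.assign.copy(), cm.UnrestrictiveGenotype
    else:
        raise TypeError("swap_operator expects a genotype")
    i, j = rng.choice(arr.size, size=2, replace=False)
    arr[i], arr[j] = arr[j], arr[i]
    return wrap(arr)


def mutation_operator(
    genotype: cm.UnrestrictiveGenotype, prob: float, rng: np.random.Generator
) -> cm.UnrestrictiveGenotype:
    """Per-position mutation of an unrestrictive genotype.

    Each amino-acid position independently mutates with probability ``prob``
    to a uniformly chosen *different* amino acid (never to stop); a position
    whose amino acid is the sole representative in the code is skipped, so
    all 20 amino acids stay present.  Stop positions are untouched.
    """
    if not isinstance(genotype, cm.UnrestrictiveGenotype):
        raise TypeError("mutation is defined only for the unrestrictive model")
    assign = genotype.assign.copy()
    hits = (rng.random(64) < prob) & (assign != cm.STOP_INDEX)
    _mutate_rows(assign[None, :], np.column_stack(np.nonzero(hits[None, :])), rng)
    return cm.UnrestrictiveGenotype(assign=assign)


def _mutate_rows(pop: np.ndarray, events: np.ndarray, rng: np.random.Generator) -> None:
    """Apply mutation events (row, position) in scan order, in place.

    Counts are consulted against the current state, so the sole-representative
    guard holds even when several positions of one individual mutate.
    """
    for i, j in events:
        old = pop[i, j]
        if int((pop[i] == old).sum()) > 1:
            new = int(rng.integers(0, 19))
            if new >= old:
                new += 1
            pop[i, j] = new


def tournament_select(
    costs: np.ndarray, window_size: int, rng: np.random.Generator
) -> int:
    """Best-of-window selection; window drawn uniformly without replacement."""
    costs = np.asarray(costs)
    if window_size < 1 or window_size > costs.size:
        raise ValueError("window_size must be in [1, population size]")
    window = np.sort(rng.choice(costs.size, size=window_size, replace=False))
    return int(window[np.argmin(costs[window])])


def _selection_costs(
    pop: np.ndarray, raw_costs: np.ndarray, cfg: GAConfig
) -> np.ndarray:
    if cfg.sharing is None:
        return raw_costs
    dm = niching.distance_matrix(pop, cfg.model)
    return niching.shared_costs(raw_costs, dm, cfg.sharing)


def step(
    population: np.ndarray,
    raw_costs: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, GenerationStats]:
    """Advance one generation; returns (new population, new raw costs, stats)."""
    n = cfg.population_size
    L = cfg.genotype_length
    sel = _selection_costs(population, raw_costs, cfg)

    # tournament: each row of idx is a sorted sample without replacement
    win = cfg.tournament_window
    idx = np.sort(rng.random((n, n)).argpartition(win - 1, axis=1)[:, :win], axis=1)
    winners = idx[np.arange(n), sel[idx].argmin(axis=1)]
    offspring = population[winners].copy()

    # swap: at most one exchange per offspring
    do_swap = rng.random(n) < cfg.swap_prob
    ns = int(do_swap.sum())
    if ns:
        a = rng.integers(0, L, size=ns)
        b = rng.integers(0, L - 1, size=ns)
        b += b >= a
        rows = np.nonzero(do_swap)[0]
        offspring[rows, a], offspring[rows, b] = offspring[rows, b], offspring[rows, a]

    if cfg.model == "unrestrictive" and cfg.mutation_prob > 0:
        if cfg.mutation_per_position:
            hits = (rng.random((n, 64)) < cfg.mutation_prob) & (
                offspring != cm.STOP_INDEX
            )
            _mutate_rows(offspring, np.column_stack(np.nonzero(hits)), rng)
        else:
            do_mut = np.nonzero(rng.random(n) < cfg.mutation_prob)[0]
            for i in do_mut:
                aa_pos = np.nonzero(offspring[i] != cm.STOP_INDEX)[0]
                j = int(rng.choice(aa_pos))
                _mutate_rows(offspring, np.array([[i, j]]), rng)

    new_costs = _raw_costs(offspring, cfg)

    if cfg.elitism:
        use_sel = cfg.elitism_cost == "selection" and cfg.sharing is not None
        elite = int(np.argmin(sel)) if use_sel else int(np.argmin(raw_costs))
        worst = int(np.argmax(new_costs))
        offspring[worst] = population[elite]
        new_costs[worst] = raw_costs[elite]

    canon = _canonical_row(cfg.model)
    stats = GenerationStats(
        generation=-1,  # filled by run()
        best_cost=float(new_costs.min()),
        mean_cost=float(new_costs.mean()),
        canonical_present=bool((offspring == canon).all(axis=1).any()),
    )
    return offspring, new_costs, stats


def _initial_population(cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.population_size
    if cfg.model == "restrictive":
        pop = rng.permuted(np.tile(np.arange(20), (n, 1)), axis=1)
    else:
        pop = np.stack([cm.random_unrestrictive(rng).assign for _ in range(n)])
    if cfg.seed_canonical:
        pop[0] = _canonical_row(cfg.model)
    return pop


def run(cfg: GAConfig) -> RunRecord:
    """Execute one GA run; fully reproducible from ``cfg.rng_seed``."""
    rng = np.random.default_rng(cfg.rng_seed)
    pop = _initial_population(cfg, rng)
    costs = _raw_costs(pop, cfg)
    canon = _canonical_row(cfg.model)
    stats = [
        GenerationStats(
            generation=0,
            best_cost=float(costs.min()),
            mean_cost=float(costs.mean()),
            canonical_present=bool((pop == canon).all(axis=1).any()),
        )
    ]
    best_i = int(np.argmin(costs))
    best_row, best_cost = pop[best_i].copy(), float(costs[best_i])
    for g in range(1, cfg.generations + 1):
        pop, costs, st = step(pop, costs, cfg, rng)
        stats.append(replace(st, generation=g))
        if st.best_cost < best_cost:
            bi = int(np.argmin(costs))
            best_row, best_cost = pop[bi].copy(), float(costs[bi])
    return RunRecord(
        config=cfg,
        stats=tuple(stats),
        final_population=pop,
        final_costs=costs,
        best_genotype=_wrap_genotype(best_row, cfg.model),
        best_cost=best_cost,
    )


def run_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed for run ``index`` under a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def multi_run(cfg: GAConfig) -> tuple[list[RunRecord], Aggregate]:
    """Independent runs with derived per-run seeds, plus ensemble aggregates."""
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = [
        run(replace(cfg, rng_seed=run_seed(cfg.rng_seed, i))) for i in range(cfg.n_runs)
    ]
    bests = np.array([r.final_best for r in records])
    means = np.array([r.final_mean for r in records])
    agg = Aggregate(
        n_runs=cfg.n_runs,
        best_mean=float(bests.mean()),
        best_sd=float(bests.std()),
        average_mean=float(means.mean()),
        average_sd=float(means.std()),
    )
    return records, agg
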