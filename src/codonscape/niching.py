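"""Fitness sharing: code distances, the sharing function, and demo benchmarks.

Fitness sharing divides the population into niches by penalizing individuals
that crowd the same region of the search space.  For a minimization problem
the shared cost is a product,

    shared_cost(i) = cost(i) * sum_j sh(d_ij),

with the triangular sharing kernel sh(d) = 1 - (d / sigma_share)^alpha for
d < sigma_share and 0 beyond; the sum runs over the whole population
including i itself, so an isolated individual keeps its raw cost.

The distance between two codes is the root squared deviation of the polar
requirements encoded at aligned genotype positions, normalized by the
maximum possible deviation Max_RSD = sqrt(L * (13.0 - 4.8)^2), with L = 20
for restrictive codes and L = 64 for unrestrictive codes.  For unrestrictive
codes, positions where either code encodes the stop signal are skipped in
the sum while L stays 64, so distances remain in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import code_model as cm

__all__ = [
    "SharingConfig",
    "code_distance",
    "distance_matrix",
    "sharing_value",
    "shared_costs",
    "five_peak_function",
    "parabola_function",
    "real_parameter_ga",
]


@dataclass(frozen=True)
class SharingConfig:
    """Sharing radius and level of the sharing kernel."""

    sigma_share: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_share <= 0:
            raise ValueError("sigma_share must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def _max_rsd(L: int, scale: cm.PolarRequirementScale) -> float:
    return float(np.sqrt(L) * (scale.max - scale.min))


def _position_values(code, scale: cm.PolarRequirementScale) -> tuple[np.ndarray, str]:
    """Polar requirement per genotype position; stops become NaN."""
    if isinstance(code, cm.RestrictiveGenotype):
        return scale.vector()[code.perm], "restrictive"
    if isinstance(code, cm.UnrestrictiveGenotype):
        x = np.where(
            code.assign == cm.STOP_INDEX, np.nan, scale.vector()[np.clip(code.assign, 0, 19)]
        )
        return x, "unrestrictive"
    raise TypeError(f"cannot interpret {type(code).__name__} as a genotype")


def code_distance(
    code_i,
    code_j,
    scale: cm.PolarRequirementScale | None = None,
    model: str | None = None,
) -> float:
    """Normalized polar-requirement distance between two codes, in [0, 1]."""
    scale = scale or cm.PolarRequirementScale()
    xi, model_i = _position_values(code_i, scale)
    xj, model_j = _position_values(code_j, scale)
    if model_i != model_j or (model is not None and model != model_i):
        raise ValueError(f"model mismatch: {model_i} vs {model_j}")
    L = xi.size
    diff2 = (xi - xj) ** 2
    return float(np.sqrt(np.nansum(diff2)) / _max_rsd(L, scale))


def distance_matrix(
    population: np.ndarray,
    model: str,
    scale: cm.PolarRequirementScale | None = None,
) -> np.ndarray:
    """Pairwise code distances of a stacked population array.

    ``population`` has shape (n, 20) of amino indices for the restrictive
    model or (n, 64) of labels (stop = 20) for the unrestrictive one.
    """
    scale = scale or cm.PolarRequirementScale()
    P = np.asarray(population)
    if model == "restrictive":
        X = scale.vector()[P]
        return squareform(pdist(X)) / _max_rsd(20, scale)
    if model == "unrestrictive":
        # stop-masked squared distance via three rank-1-style matmuls:
        # d2_ij = sum_k m_ik m_jk (x_ik - x_jk)^2
        M = (P != cm.STOP_INDEX).astype(float)
        X = scale.vector()[np.clip(P, 0, 19)] * M
        A = X ** 2  # already masked since X is
        d2 = A @ M.T + M @ A.T - 2.0 * (X @ X.T)
        d2 = 0.5 * (d2 + d2.T)  # enforce exact symmetry
        np.fill_diagonal(d2, 0.0)
        np.maximum(d2, 0.0, out=d2)
        return np.sqrt(d2) / _max_rsd(64, scale)
    raise ValueError(f"unknown model {model!r}")


def sharing_value(d: float | np.ndarray, cfg: SharingConfig) -> float | np.ndarray:
    """Sharing kernel: 1 - (d / sigma)^alpha below the radius, 0 beyond."""
    d = np.asarray(d, dtype=float)
    out = np.where(d < cfg.sigma_share, 1.0 - (d / cfg.sigma_share) ** cfg.alpha, 0.0)
    return float(out) if out.ndim == 0 else out


def shared_costs(
    costs: np.ndarray, dmat: np.ndarray, cfg: SharingConfig
) -> np.ndarray:
    """Multiplicative shared costs for a minimization problem.

    Each cost is inflated by its niche count sum_j sh(d_ij) (self included),
    so crowded regions pay a selection penalty while isolated individuals are
    unaffected.
    """
    costs = np.asarray(costs, dtype=float)
    dmat = np.asarray(dmat, dtype=float)
    if dmat.shape != (costs.size, costs.size):
        raise ValueError("distance matrix dimension does not match costs")
    niche = sharing_value(dmat, cfg).sum(axis=1)
    return costs * niche


# ---------------------------------------------------------------------------
# real-parameter demo functions and GA


def five_peak_function(x):
    """Decreasing-maxima niching benchmark on [0, 1].

    Five unequally spaced peaks of decreasing height, with local maxima near
    x = 0.080, 0.247, 0.451, 0.681 and 0.934; the first is the global
    maximum.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("five_peak_function is defined on [0, 1]")
    env = np.exp(-2.0 * np.log(2.0) * ((x - 0.08) / 0.854) ** 2)
    out = env * np.sin(5.0 * np.pi * (x ** 0.75 - 0.05)) ** 6
    return float(out) if out.ndim == 0 else out


def parabola_function(x):
    """The unimodal demo objective 1 + x^2 on [-1, 1]."""
    x = np.asarray(x, dtype=float)
    out = 1.0 + x ** 2
    return float(out) if out.ndim == 0 else out


def real_parameter_ga(
    objective,
    domain: tuple[float, float],
    minimize: bool,
    sharing: SharingConfig | None = None,
    population_size: int = 100,
    generations: int = 100,
    mutation_prob: float = 0.25,
    mutation_width: float = 0.02,
    tournament_fraction: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small scalar-parameter GA used to demonstrate niching behavior.

    Mutation perturbs x to a random close value (a uniform step of half-width
    ``mutation_width``, clipped to the domain); selection is tournament over
    the shared (or raw) objective.  With sharing active, niche counts are
    *continuously updated*: each tournament evaluates candidates against the
    offspring already placed in the next generation.  Plain parent-population
    sharing combined with tournament selection is known to lose the lower
    niches to drift; continuous updating is the standard stabilization and
    yields niche occupancies proportional to peak fitness.

    Returns the final population and its raw objective values.
    """
    rng = np.random.default_rng(seed)
    lo, hi = domain
    x = rng.uniform(lo, hi, size=population_size)
    window = max(1, round(tournament_fraction * population_size))
    for _ in range(generations):
        f = np.asarray(objective(x), dtype=float)
        new = np.empty(population_size)
        for i in range(population_size):
            cand = np.sort(rng.choice(population_size, size=window, replace=False))
            if sharing is not None:
                if i:
                    d = np.abs(x[cand][:, None] - new[None, :i])
                    niche = sharing_value(d, sharing).sum(axis=1) + 1.0  # + self
                else:
                    niche = np.ones(window)
                sel = f[cand] * niche if minimize else -(f[cand] / niche)
            else:
                sel = f[cand] if minimize else -f[cand]
            new[i] = x[cand[np.argmin(sel)]]
        mut = rng.random(population_size) < mutation_prob
        new[mut] += rng.uniform(-mutation_width, mutation_width, size=int(mut.sum()))
        np.clip(new, lo, hi, out=new)
        x = new
    return x, np.asarray(objective(x), dtype=float)
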