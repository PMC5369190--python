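"""Landscape diagnostics over GA populations.

These analyses locate the canonical genetic code within the cost landscape
explored by the GA: how far evolved populations sit from the canonical code,
how spread out they are among themselves (inter-distance histograms, the
signature of niching or its absence), whether a seeded canonical genotype
survives selection, and the percentage distance minimization computed from a
run ensemble plus a random-code sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import code_model as cm
from . import error_cost as ec
from . import evolution as ev
from . import niching

__all__ = [
    "DistanceScatter",
    "InterdistanceHistogram",
    "distances_to_canonical",
    "interdistance_histogram",
    "canonical_survival",
    "pdm_from_ensemble",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class DistanceScatter:
    """Per-individual (distance to canonical, raw cost) pairs."""

    distances: np.ndarray
    costs: np.ndarray


@dataclass(frozen=True)
class InterdistanceHistogram:
    """Counts of unordered pair distances in 100 bins of width 0.01.

    Bins are [0, 0.01), ..., [0.98, 0.99), [0.99, 1.0] — the last bin is
    closed so the theoretical maximum distance 1 is not lost.
    """

    counts: np.ndarray

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, 101)


def distances_to_canonical(
    snapshot: np.ndarray,
    model: str,
    scheme: str = "ms",
    scale: cm.PolarRequirementScale | None = None,
) -> DistanceScatter:
    """Distance of every individual to the canonical genotype, with raw cost."""
    snapshot = np.asarray(snapshot)
    canon = np.arange(20) if model == "restrictive" else cm.canonical_assignment()
    both = np.vstack([canon[None, :], snapshot])
    dm = niching.distance_matrix(both, model, scale=scale)
    if model == "restrictive":
        costs = ec.permutation_costs(snapshot, weights=scheme, scale=scale)
    else:
        costs = ec.assignment_costs(snapshot, weights=scheme, scale=scale)
    return DistanceScatter(distances=dm[0, 1:], costs=costs)


def interdistance_histogram(
    snapshot: np.ndarray,
    model: str,
    scale: cm.PolarRequirementScale | None = None,
) -> InterdistanceHistogram:
    """Histogram of all N(N-1)/2 pairwise code distances of a snapshot."""
    dm = niching.distance_matrix(np.asarray(snapshot), model, scale=scale)
    pairs = dm[np.triu_indices(dm.shape[0], k=1)]
    counts, _ = np.histogram(pairs, bins=np.linspace(0.0, 1.0, 101))
    return InterdistanceHistogram(counts=counts)


def canonical_survival(record: ev.RunRecord) -> int | str:
    """First generation at which the canonical genotype is gone.

    Presence is exact genotype equality, tracked per generation in the run
    record.  Returns the generation index of first absence, or ``"survived"``
    if the canonical code is still present at the final generation.
    """
    if not record.config.seed_canonical:
        raise ValueError("run was not executed with seed_canonical")
    for st in record.stats:
        if not st.canonical_present:
            return st.generation
    return "survived"


def pdm_from_ensemble(
    records: list[ev.RunRecord],
    random_sample_stats: ec.SampleStats,
) -> float:
    """p.d.m. of the canonical code from a GA ensemble and random-code stats.

    delta_code is the canonical cost under the ensemble's scheme, delta_mean
    the random-code mean, delta_low the best raw cost seen in any run.
    """
    if not records:
        raise ValueError("need at least one run record")
    scheme = records[0].config.scheme
    delta_low = min(r.best_cost for r in records)
    return ec.pdm(
        delta_code=ec.canonical_cost(weights=scheme),
        delta_mean=random_sample_stats.mean,
        delta_low=delta_low,
    )


def summarize_ensemble(records: list[ev.RunRecord]) -> dict[str, float]:
    """Mean and sd of final best / final average over an ensemble of runs.

    All records must share a configuration up to the seed.  Values are
    rounded to 2 decimals, the precision of the reference tables.
    """
    if not records:
        raise ValueError("need at least one run record")
    ref = records[0].config
    for r in records[1:]:
        a = {k: v for k, v in vars(r.config).items() if k != "rng_seed"}
        b = {k: v for k, v in vars(ref).items() if k != "rng_seed"}
        if a != b:
            raise ValueError("records have mixed configurations")
    bests = np.array([r.final_best for r in records])
    means = np.array([r.final_mean for r in records])
    return {
        "best_mean": round(float(bests.mean()), 2),
        "best_sd": round(float(bests.std()), 2),
        "average_mean": round(float(means.mean()), 2),
        "average_sd": round(float(means.std()), 2),
    }
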