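"""Error-minimization cost of a genetic code and random-code statistics.

The cost of a code is the weighted mean squared change in polar requirement
over all single-base substitutions between its codons,

    cost = sum_e w_e (X_src(e) - X_dst(e))^2  /  sum_e w_e,

where e runs over the 576 ordered single-base codon changes, events whose
source or target codon carries the stop signal are excluded, synonymous
events are retained (they add weight to the denominator but 0 to the
numerator), and w_e depends on the codon position and the transition /
transversion class of the base change.  With all weights equal to 1 this is
the classic MS measure (canonical code: 5.19); with the mistranslation
weights of the tMS scheme (position 1: ts 1 / tv 0.5, position 2: ts 0.5 /
tv 0.1, position 3: ts 1 / tv 1) it is tMS (canonical code: 2.63).

Lower cost means a more robust ("better adapted") code, so the genetic
algorithm in :mod:`codonscape.evolution` minimizes it.

The percentage distance minimization (p.d.m.) locates the canonical code's
cost linearly between the random-code mean and the best known cost:

    p.d.m. = (mean - code) / (mean - low) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np

from . import code_model as cm

__all__ = [
    "WeightScheme",
    "MS_SCHEME",
    "TMS_SCHEME",
    "get_scheme",
    "SubstitutionEvent",
    "enumerate_substitutions",
    "ms_error",
    "CostSummary",
    "pdm",
    "SampleStats",
    "sample_random_statistics",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


def is_transition(b1: str, b2: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine changes."""
    pair = {b1, b2}
    return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass(frozen=True)
class WeightScheme:
    """Per-codon-position transition/transversion substitution weights.

    ``w[(position, klass)]`` with position in {1, 2, 3} and klass in
    {"transition", "transversion"}.
    """

    name: str
    w: Mapping[tuple[int, str], float]

    def weight(self, position: int, transition: bool) -> float:
        return self.w[(position, "transition" if transition else "transversion")]


MS_SCHEME = WeightScheme(
    name="ms",
    w={(p, k): 1.0 for p in (1, 2, 3) for k in ("transition", "transversion")},
)
TMS_SCHEME = WeightScheme(
    name="tms",
    w={
        (1, "transition"): 1.0, (1, "transversion"): 0.5,
        (2, "transition"): 0.5, (2, "transversion"): 0.1,
        (3, "transition"): 1.0, (3, "transversion"): 1.0,
    },
)
_SCHEMES = {"ms": MS_SCHEME, "tms": TMS_SCHEME}


def get_scheme(scheme: str | WeightScheme) -> WeightScheme:
    if isinstance(scheme, WeightScheme):
        return scheme
    try:
        return _SCHEMES[scheme.lower()]
    except KeyError:
        raise ValueError(f"unknown weight scheme {scheme!r}; use 'ms' or 'tms'") from None


@dataclass(frozen=True)
class SubstitutionEvent:
    """One single-base codon change between two non-stop codons."""

    source_codon: str
    target_codon: str
    source_label: str
    target_label: str
    codon_position: int  # 1-based
    mutation_class: str  # "transition" | "transversion"


@lru_cache(maxsize=None)
def _event_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The 576 ordered single-base codon changes as parallel arrays.

    Returns (source codon index, target codon index, 1-based position,
    transition flag); stop filtering is code-dependent and applied later.
    """
    src, dst, pos, ts = [], [], [], []
    for ci, codon in enumerate(cm.CODONS):
        for p in range(3):
            for b in cm.BASES:
                if b == codon[p]:
                    continue
                other = codon[:p] + b + codon[p + 1:]
                src.append(ci)
                dst.append(cm.CODON_INDEX[other])
                pos.append(p + 1)
                ts.append(is_transition(codon[p], b))
    return (
        np.array(src), np.array(dst), np.array(pos), np.array(ts, dtype=bool),
    )


@lru_cache(maxsize=None)
def _event_weights(scheme_name: str) -> np.ndarray:
    scheme = get_scheme(scheme_name)
    _, _, pos, ts = _event_arrays()
    return np.array(
        [scheme.weight(int(p), bool(t)) for p, t in zip(pos, ts)], dtype=float
    )


def enumerate_substitutions(code) -> list[SubstitutionEvent]:
    """All single-base substitution events of a code, stop events excluded.

    The raw enumeration covers 64 codons x 9 neighbours = 576 ordered events;
    events whose source or target label is the stop signal are dropped.
    Synonymous events (same amino acid on both sides) are retained.
    """
    table = _as_table(code)
    src, dst, pos, ts = _event_arrays()
    events = []
    for s, d, p, t in zip(src, dst, pos, ts):
        a1, a2 = table[cm.CODONS[s]], table[cm.CODONS[d]]
        if a1 == cm.STOP or a2 == cm.STOP:
            continue
        events.append(
            SubstitutionEvent(
                source_codon=cm.CODONS[s],
                target_codon=cm.CODONS[d],
                source_label=a1,
                target_label=a2,
                codon_position=int(p),
                mutation_class="transition" if t else "transversion",
            )
        )
    return events


def _as_table(code) -> dict[str, str]:
    if isinstance(code, cm.RestrictiveGenotype):
        return cm.expand(code)
    if isinstance(code, cm.UnrestrictiveGenotype):
        return cm.from_compact(cm.to_compact(code))
    if isinstance(code, Mapping):
        return dict(code)
    raise TypeError(f"cannot interpret {type(code).__name__} as a code")


def _as_label_array(code) -> np.ndarray:
    if isinstance(code, cm.RestrictiveGenotype):
        return cm.expand_assignment(code.perm)
    if isinstance(code, cm.UnrestrictiveGenotype):
        return code.assign
    if isinstance(code, Mapping):
        return np.array(
            [cm.STOP_INDEX if code[c] == cm.STOP else cm.AMINO_INDEX[code[c]]
             for c in cm.CODONS],
            dtype=np.int64,
        )
    code = np.asarray(code)
    if code.shape == (64,):
        return code.astype(np.int64)
    raise TypeError("expected a genotype, codon->label mapping, or length-64 array")


def ms_error(
    code,
    scale: cm.PolarRequirementScale | None = None,
    weights: str | WeightScheme = MS_SCHEME,
) -> float:
    """Weighted mean squared polar-requirement change of a code.

    ``code`` may be a genotype of either model, a codon -> label mapping, or a
    length-64 integer label array.  The denominator is the weighted count of
    included (non-stop) events, so the statistic is a true weighted mean and
    reduces to the plain event-count average under the equal-weight scheme.

    Genotypes must satisfy their full model invariants.  Plain mappings are
    only checked structurally (64 known codons, known labels): the cost of a
    reduced code — fewer than 20 amino acids, relocated or extra stops — is
    still well defined, and such toy codes are useful for validation.
    """
    if isinstance(code, (cm.RestrictiveGenotype, cm.UnrestrictiveGenotype)):
        violations = cm.validate(code)
    elif isinstance(code, Mapping):
        structural_only = {"missing_amino_acid", "stop_codons_not_canonical", "stop_count"}
        violations = [v for v in cm.validate(code) if v not in structural_only]
    else:
        violations = []
    if violations:
        raise ValueError(f"invalid code: {violations}")
    labels = _as_label_array(code)
    return float(assignment_costs(labels[None, :], scale=scale, weights=weights)[0])


def assignment_costs(
    assignments: np.ndarray,
    scale: cm.PolarRequirementScale | None = None,
    weights: str | WeightScheme = MS_SCHEME,
) -> np.ndarray:
    """Vectorized cost of a batch of length-64 label arrays (stop = 20)."""
    scale = scale or cm.PolarRequirementScale()
    scheme = get_scheme(weights)
    src, dst, _, _ = _event_arrays()
    w = _event_weights(scheme.name)
    A = np.asarray(assignments)
    X = scale.vector()[np.clip(A, 0, 19)]
    ok = (A[:, src] != cm.STOP_INDEX) & (A[:, dst] != cm.STOP_INDEX)
    wv = w * ok
    num = (wv * (X[:, src] - X[:, dst]) ** 2).sum(axis=1)
    return num / wv.sum(axis=1)


@lru_cache(maxsize=None)
def _block_quadratic(scheme_name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Restrictive fast path: cost(perm) as a quadratic form over blocks.

    W[a, b] accumulates the weight of non-stop events from a codon of
    canonical block a to one of block b; with amino values x = X[perm],
    cost = (sum_a s_a x_a^2 - 2 x' W x) / D where s = row + column sums of W
    and D is the total included weight.  Exact, because in a restrictive code
    two codons are synonymous iff they lie in the same canonical block.
    """
    scheme = get_scheme(scheme_name)
    blocks = cm.codon_blocks()
    block_of = np.empty(64, dtype=np.int64)
    for k, b in enumerate(blocks.blocks):
        block_of[list(b)] = k
    block_of[list(blocks.stop_block)] = 20
    src, dst, _, _ = _event_arrays()
    w = _event_weights(scheme.name)
    W = np.zeros((20, 20))
    D = 0.0
    for s, d, we in zip(src, dst, w):
        a, b = block_of[s], block_of[d]
        if a == 20 or b == 20:
            continue
        W[a, b] += we
        D += we
    return W, W.sum(axis=0) + W.sum(axis=1), D


def permutation_costs(
    perms: np.ndarray,
    scale: cm.PolarRequirementScale | None = None,
    weights: str | WeightScheme = MS_SCHEME,
) -> np.ndarray:
    """Vectorized cost of a batch of restrictive permutations, shape (n, 20)."""
    scale = scale or cm.PolarRequirementScale()
    scheme = get_scheme(weights)
    W, s, D = _block_quadratic(scheme.name)
    X = scale.vector()[np.asarray(perms)]
    return ((X ** 2 * s).sum(axis=1) - 2.0 * np.einsum("ni,ij,nj->n", X, W, X)) / D


def canonical_cost(weights: str | WeightScheme = MS_SCHEME,
                   scale: cm.PolarRequirementScale | None = None) -> float:
    """Cost of the standard genetic code under the given scheme."""
    return float(
        assignment_costs(cm.canonical_assignment()[None, :], scale=scale, weights=weights)[0]
    )


@dataclass(frozen=True)
class CostSummary:
    """The three quantities entering the p.d.m. statistic."""

    delta_code: float
    delta_mean: float
    delta_low: float
    n_samples: int = 0


def pdm(
    summary: CostSummary | None = None,
    *,
    delta_code: float | None = None,
    delta_mean: float | None = None,
    delta_low: float | None = None,
) -> float:
    """Percentage distance minimization: (mean - code) / (mean - low) * 100.

    100 means the code is as good as the best known one, 0 that it is no
    better than a random code; values outside [0, 100] are possible for codes
    outside that bracket.
    """
    if summary is not None:
        delta_code, delta_mean, delta_low = (
            summary.delta_code, summary.delta_mean, summary.delta_low,
        )
    if delta_mean == delta_low:
        raise ZeroDivisionError("p.d.m. undefined: delta_mean equals delta_low")
    return (delta_mean - delta_code) / (delta_mean - delta_low) * 100.0


@dataclass(frozen=True)
class SampleStats:
    """Random-code population statistics under one model and scheme."""

    mean: float
    sd: float
    count_better: int
    canonical_cost: float
    n: int


def sample_random_statistics(
    model: str,
    scheme: str | WeightScheme,
    n: int,
    rng: np.random.Generator,
    chunk: int = 100_000,
) -> SampleStats:
    """Score ``n`` random codes; count those strictly better than canonical.

    This reproduces the classic statistical test of code optimality: among a
    large sample of random codes, how many have a lower error cost than the
    standard code?  Streaming in chunks keeps memory flat at large ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    canon = canonical_cost(weights=scheme)
    total = 0.0
    total_sq = 0.0
    better = 0
    done = 0
    while done < n:
        m = min(chunk, n - done)
        if model == "restrictive":
            perms = rng.permuted(np.tile(np.arange(20), (m, 1)), axis=1)
            costs = permutation_costs(perms, weights=scheme)
        elif model == "unrestrictive":
            A = np.stack([cm.random_unrestrictive(rng).assign for _ in range(m)])
            costs = assignment_costs(A, weights=scheme)
        else:
            raise ValueError(f"unknown model {model!r}")
        total += costs.sum()
        total_sq += (costs ** 2).sum()
        better += int((costs < canon).sum())
        done += m
    mean = total / n
    var = max(total_sq / n - mean ** 2, 0.0)
    return SampleStats(
        mean=float(mean), sd=float(np.sqrt(var)), count_better=better,
        canonical_cost=canon, n=n,
    )
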