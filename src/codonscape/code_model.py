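"""Hypothetical genetic codes: representation, generation, validation, serialization.

Two models of alternative codes are supported:

* **restrictive** — the 64 codons keep the canonical block structure (the 21
  synonymous codon sets of the standard code, including the fixed stop set
  {UAA, UAG, UGA}); an alternative code is a permutation of the 20 amino acids
  over the 20 amino-acid blocks.
* **unrestrictive** — any assignment of labels to the 64 codons subject to two
  constraints: exactly 3 codons carry the stop signal and every one of the 20
  amino acids is encoded at least once.

Amino acids are indexed 0..19 in alphabetical order of their three-letter
names (Ala, Arg, Asn, ..., Val); index 20 (:data:`STOP_INDEX`) is the stop
signal.  Codons are RNA triplets over U, C, A, G, indexed lexicographically
with base order U < C < A < G, so codon 0 is UUU and codon 63 is GGG.  Both
orderings are fixed because genotype position semantics and the on-disk
formats depend on them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "BASES",
    "CODONS",
    "AMINO_ACIDS",
    "AMINO_ACID_NAMES",
    "STOP",
    "STOP_INDEX",
    "STOP_CODONS",
    "POLAR_REQUIREMENT",
    "PolarRequirementScale",
    "CodonBlockStructure",
    "RestrictiveGenotype",
    "UnrestrictiveGenotype",
    "canonical_code",
    "canonical_assignment",
    "codon_blocks",
    "random_restrictive",
    "random_unrestrictive",
    "expand",
    "count_codes",
    "validate",
    "to_compact",
    "from_compact",
    "write_code_table",
    "read_code_table",
]

BASES = "UCAG"
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: One-letter codes in alphabetical order of the three-letter names.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AMINO_ACID_NAMES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
AMINO_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
STOP = "*"
STOP_INDEX = 20
STOP_CODONS = ("UAA", "UAG", "UGA")

# Woese polar requirement (water/pyridine partition coefficient), the single
# amino-acid property used throughout: it defines both the error cost and the
# code distance.  Extremes: Asp 13.0 (max), Cys 4.8 (min).
POLAR_REQUIREMENT: dict[str, float] = {
    "A": 7.0, "R": 9.1, "N": 10.0, "D": 13.0, "C": 4.8,
    "Q": 8.6, "E": 12.5, "G": 7.9, "H": 8.4, "I": 4.9,
    "L": 4.9, "K": 10.1, "M": 5.3, "F": 5.0, "P": 6.6,
    "S": 7.5, "T": 6.6, "W": 5.2, "Y": 5.4, "V": 5.6,
}

# Standard genetic code as a 64-character string in codon-index order
# (U row, C row, A row, G row of the conventional translation table).
_CANONICAL_COMPACT = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)


@dataclass(frozen=True)
class PolarRequirementScale:
    """Amino acid -> polar requirement mapping used as the cost property."""

    values: Mapping[str, float] = field(default_factory=lambda: dict(POLAR_REQUIREMENT))

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError("scale must cover exactly the 20 standard amino acids")

    def vector(self) -> np.ndarray:
        """Values as a length-20 array in the fixed amino-acid order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    @property
    def max(self) -> float:
        return max(self.values.values())

    @property
    def min(self) -> float:
        return min(self.values.values())


@dataclass(frozen=True)
class CodonBlockStructure:
    """The 21 synonymous codon sets of the canonical code.

    ``blocks[k]`` (k = 0..19) lists the codon indices coding amino acid k in
    the canonical table; ``stop_block`` is the fixed stop set.  Position k of a
    restrictive genotype names the amino acid assigned to ``blocks[k]``.
    """

    blocks: tuple[tuple[int, ...], ...]
    stop_block: tuple[int, ...]

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)


@dataclass(frozen=True)
class RestrictiveGenotype:
    """A permutation of the 20 amino acids over the 20 canonical codon blocks."""

    perm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "perm", np.asarray(self.perm, dtype=np.int64))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RestrictiveGenotype) and np.array_equal(self.perm, other.perm)

    def __hash__(self) -> int:
        return hash(self.perm.tobytes())


@dataclass(frozen=True)
class UnrestrictiveGenotype:
    """A length-64 label assignment (amino index 0..19, or 20 for stop)."""

    assign: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "assign", np.asarray(self.assign, dtype=np.int64))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, UnrestrictiveGenotype) and np.array_equal(self.assign, other.assign)

    def __hash__(self) -> int:
        return hash(self.assign.tobytes())


Genotype = Union[RestrictiveGenotype, UnrestrictiveGenotype]


def canonical_code() -> dict[str, str]:
    """The standard translation table as a codon -> one-letter-label dict."""
    return {c: _CANONICAL_COMPACT[i] for i, c in enumerate(CODONS)}


def canonical_assignment() -> np.ndarray:
    """Standard code as a length-64 integer label array (stop = 20)."""
    return np.array(
        [STOP_INDEX if a == STOP else AMINO_INDEX[a] for a in _CANONICAL_COMPACT],
        dtype=np.int64,
    )


def codon_blocks(table: Mapping[str, str] | None = None) -> CodonBlockStructure:
    """Partition the 64 codons into the 21 synonymous sets of ``table``.

    Amino-acid blocks are ordered alphabetically by three-letter name (the
    fixed amino index), which pins down restrictive genotype semantics.
    """
    if table is None:
        table = canonical_code()
    blocks: list[list[int]] = [[] for _ in range(20)]
    stop_block: list[int] = []
    for codon, label in table.items():
        if label == STOP:
            stop_block.append(CODON_INDEX[codon])
        else:
            blocks[AMINO_INDEX[label]].append(CODON_INDEX[codon])
    return CodonBlockStructure(
        blocks=tuple(tuple(sorted(b)) for b in blocks),
        stop_block=tuple(sorted(stop_block)),
    )


def random_restrictive(rng: np.random.Generator) -> RestrictiveGenotype:
    """Uniformly random amino-acid permutation over the 20 codon blocks."""
    return RestrictiveGenotype(perm=rng.permutation(20))


def random_unrestrictive(rng: np.random.Generator) -> UnrestrictiveGenotype:
    """Random 64-codon assignment with 3 stops and all 20 amino acids present.

    Construction: 3 stop positions and 20 "anchor" positions (one per amino
    acid, in a random order) are drawn uniformly without replacement from the
    64; the remaining 41 positions are filled i.i.d. uniform over the 20 amino
    acids.
    """
    assign = rng.integers(0, 20, size=64, dtype=np.int64)
    special = rng.choice(64, size=23, replace=False)
    assign[special[:3]] = STOP_INDEX
    assign[special[3:]] = rng.permutation(20)
    return UnrestrictiveGenotype(assign=assign)


def expand(
    genotype: RestrictiveGenotype | np.ndarray,
    blocks: CodonBlockStructure | None = None,
) -> dict[str, str]:
    """Expand a restrictive genotype into a full codon -> label table."""
    if blocks is None:
        blocks = codon_blocks()
    perm = genotype.perm if isinstance(genotype, RestrictiveGenotype) else np.asarray(genotype)
    table: dict[str, str] = {}
    for k, block in enumerate(blocks.blocks):
        for ci in block:
            table[CODONS[ci]] = AMINO_ACIDS[perm[k]]
    for ci in blocks.stop_block:
        table[CODONS[ci]] = STOP
    return {c: table[c] for c in CODONS}


def expand_assignment(perm: np.ndarray, blocks: CodonBlockStructure | None = None) -> np.ndarray:
    """Vector form of :func:`expand`: permutation(s) -> length-64 label array(s).

    Accepts a single permutation of shape (20,) or a batch of shape (n, 20).
    """
    if blocks is None:
        blocks = codon_blocks()
    perm = np.asarray(perm)
    block_of_codon = np.empty(64, dtype=np.int64)  # amino block index, 20 for stop
    for k, block in enumerate(blocks.blocks):
        block_of_codon[list(block)] = k
    block_of_codon[list(blocks.stop_block)] = 20
    padded = np.concatenate(
        [perm, np.full(perm.shape[:-1] + (1,), STOP_INDEX, dtype=np.int64)], axis=-1
    )
    return padded[..., block_of_codon]


def count_codes(model: str) -> int:
    """Size of the restrictive code space: 20! permutations."""
    if model != "restrictive":
        raise ValueError(
            "count_codes supports only the restrictive model; other counts are not computed"
        )
    return math.factorial(20)


def _as_assignment(code) -> np.ndarray | None:
    if isinstance(code, UnrestrictiveGenotype):
        return code.assign
    if isinstance(code, Mapping):
        try:
            return np.array(
                [STOP_INDEX if code[c] == STOP else AMINO_INDEX[code[c]] for c in CODONS],
                dtype=np.int64,
            )
        except KeyError:
            return None
    return None


def validate(code) -> list[str]:
    """Check model invariants; returns a (possibly empty) list of violation names.

    Accepts a :class:`RestrictiveGenotype`, an :class:`UnrestrictiveGenotype`,
    or a full codon -> label mapping.  Violations are data, not exceptions.
    """
    violations: list[str] = []
    if isinstance(code, RestrictiveGenotype):
        perm = code.perm
        if perm.shape != (20,):
            violations.append("wrong_length")
        elif not np.array_equal(np.sort(perm), np.arange(20)):
            violations.append("not_permutation")
        return violations

    if isinstance(code, Mapping):
        if set(code) != set(CODONS):
            return ["bad_codon_set"]
        unknown = {l for l in code.values() if l != STOP and l not in AMINO_INDEX}
        if unknown:
            return ["unknown_label"]
    assign = _as_assignment(code)
    if assign is None:
        return ["unrecognized_code"]
    if assign.shape != (64,):
        return ["wrong_length"]
    if int((assign == STOP_INDEX).sum()) != 3:
        violations.append("stop_count")
    present = np.unique(assign[assign != STOP_INDEX])
    if len(present) != 20:
        violations.append("missing_amino_acid")
    if isinstance(code, Mapping):
        # full tables additionally pin the stop codons to the canonical three
        stops = {c for c, l in code.items() if l == STOP}
        if stops != set(STOP_CODONS):
            violations.append("stop_codons_not_canonical")
    return violations


# ---------------------------------------------------------------------------
# serialization


def _labels_of(code) -> str:
    if isinstance(code, RestrictiveGenotype):
        table = expand(code)
        return "".join(table[c] for c in CODONS)
    if isinstance(code, UnrestrictiveGenotype):
        return "".join(
            STOP if int(a) == STOP_INDEX else AMINO_ACIDS[int(a)] for a in code.assign
        )
    if isinstance(code, Mapping):
        return "".join(code[c] for c in CODONS)
    raise TypeError(f"cannot serialize {type(code).__name__}")


def to_compact(code) -> str:
    """Serialize a code as a 64-character label string in codon-index order."""
    return _labels_of(code)


def from_compact(s: str) -> dict[str, str]:
    """Inverse of :func:`to_compact`; returns a codon -> label dict."""
    s = s.strip()
    if len(s) != 64:
        raise ValueError(f"compact code must have 64 characters, got {len(s)}")
    for ch in s:
        if ch != STOP and ch not in AMINO_INDEX:
            raise ValueError(f"unknown label {ch!r}")
    return {c: s[i] for i, c in enumerate(CODONS)}


def write_code_table(code, path: str | Path) -> None:
    """Write a code as 64 TSV lines ``codon<TAB>label`` in codon-index order."""
    labels = _labels_of(code)
    Path(path).write_text(
        "".join(f"{c}\t{labels[i]}\n" for i, c in enumerate(CODONS))
    )


def read_code_table(path: str | Path) -> dict[str, str]:
    """Read the TSV code-table format, verifying structure as it parses."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != 64:
        raise ValueError(f"code table must have 64 lines, got {len(lines)}")
    table: dict[str, str] = {}
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed line: {ln!r}")
        codon, label = parts[0].strip(), parts[1].strip()
        if codon not in CODON_INDEX:
            raise ValueError(f"unknown codon {codon!r}")
        if codon in table:
            raise ValueError(f"duplicate codon {codon!r}")
        if label != STOP and label not in AMINO_INDEX:
            raise ValueError(f"unknown label {label!r}")
        table[codon] = label
    return {c: table[c] for c in CODONS}
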