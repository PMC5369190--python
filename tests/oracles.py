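"""Independent brute-force oracles, deliberately sharing no code with the package.

Everything here is written with plain Python dicts, strings and loops: its
own codon list, its own transition rule, its own weight table.  It exists so
the vectorized implementations can be checked against an enumeration that a
reviewer can follow line by line.
"""

from itertools import product

ORACLE_BASES = "UCAG"
ORACLE_CODONS = ["".join(t) for t in product(ORACLE_BASES, repeat=3)]

ORACLE_POLAR = {
    "A": 7.0, "R": 9.1, "N": 10.0, "D": 13.0, "C": 4.8,
    "Q": 8.6, "E": 12.5, "G": 7.9, "H": 8.4, "I": 4.9,
    "L": 4.9, "K": 10.1, "M": 5.3, "F": 5.0, "P": 6.6,
    "S": 7.5, "T": 6.6, "W": 5.2, "Y": 5.4, "V": 5.6,
}

ORACLE_TMS = {
    (1, True): 1.0, (1, False): 0.5,
    (2, True): 0.5, (2, False): 0.1,
    (3, True): 1.0, (3, False): 1.0,
}


def oracle_cost(table, scheme="ms", prop=None):
    """Weighted mean squared property change by explicit 576-event enumeration.

    ``table`` maps each of the 64 codons to a one-letter amino acid or "*".
    """
    prop = prop or ORACLE_POLAR
    num = 0.0
    den = 0.0
    n_raw = 0
    for codon in ORACLE_CODONS:
        for pos in (0, 1, 2):
            for base in ORACLE_BASES:
                if base == codon[pos]:
                    continue
                n_raw += 1
                mutant = codon[:pos] + base + codon[pos + 1:]
                a, b = table[codon], table[mutant]
                if a == "*" or b == "*":
                    continue
                transition = {codon[pos], base} in ({"A", "G"}, {"C", "U"})
                w = 1.0 if scheme == "ms" else ORACLE_TMS[(pos + 1, transition)]
                num += w * (prop[a] - prop[b]) ** 2
                den += w
    assert n_raw == 576
    return num / den


def oracle_distance(table_i, table_j, length):
    """Root-squared-deviation code distance by direct position-wise loop."""
    total = 0.0
    for codon in ORACLE_CODONS:
        a, b = table_i[codon], table_j[codon]
        if a == "*" or b == "*":
            continue
        total += (ORACLE_POLAR[a] - ORACLE_POLAR[b]) ** 2
    max_rsd = (length * (13.0 - 4.8) ** 2) ** 0.5
    return total ** 0.5 / max_rsd
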