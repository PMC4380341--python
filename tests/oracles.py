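"""Independent oracles used by the test suite.

Each oracle is deliberately written from first principles (brute force,
exact rational arithmetic, or a frozen reference table) so it shares no
code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from poolsweep.io_formats import GeneModel, ReferenceGenome, reverse_complement


def pair_mismatch_fraction(counts: dict) -> float:
    """Fraction of mismatching unordered read pairs, by enumeration."""
    reads = [b for b, c in counts.items() for _ in range(c)]
    pairs = list(itertools.combinations(reads, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def tajima_constants_fraction_oracle(n: int) -> dict[str, Fraction]:
    """Exact-rational evaluation of the Tajima (1989) constants."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


# The standard genetic code as the classic 64-character string in TCAG
# order -- frozen here, not derived from any library or the implementation.
ORACLE_ORDER = "TCAG"
ORACLE_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


def oracle_aa(codon: str) -> str:
    i, j, k = (ORACLE_ORDER.index(b) for b in codon)
    return ORACLE_AA[16 * i + 4 * j + k]


def oracle_kind(ref_codon: str, alt_codon: str) -> str:
    a, b = oracle_aa(ref_codon), oracle_aa(alt_codon)
    if a == b:
        return "synonymous"
    if b == "*" and a != "*":
        return "nonsense"
    return "nonsynonymous"


def codon_reference() -> tuple[ReferenceGenome, GeneModel, GeneModel]:
    """All 64 codons as one plus-strand gene, and the same coding sequence
    readable from a minus-strand gene elsewhere on the chromosome."""
    cds = "".join(ALL_CODONS)  # 192 bp
    seq = "ACGTACGTAC" + cds + "ACGTACGTAC" + reverse_complement(cds) + "ACGT"
    ref = ReferenceGenome({"2L": seq})
    plus = GeneModel("gplus", "2L", "+", [(11, 11 + 192 - 1)])
    minus = GeneModel("gminus", "2L", "-", [(213, 213 + 192 - 1)])
    return ref, plus, minus
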