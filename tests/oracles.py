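"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: position-by-
position scanning, exact rational hypergeometric sums, a hand-written codon
table — so the oracles share no code path with the implementation they
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_iupac_scan(seq: str, pattern: str) -> list[int]:
    """O(n*m) position-by-position IUPAC matcher."""
    hits = []
    m = len(pattern)
    for start in range(len(seq) - m + 1):
        if all(seq[start + i] in IUPAC[pattern[i]] for i in range(m)):
            hits.append(start)
    return hits


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric
    point probabilities not exceeding that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return Fraction(1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return total


# hand-written standard genetic code ('*' = stop), independent of Biopython
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def consequence_oracle(ref_codon: str, pos_in_codon: int, alt_base: str) -> str:
    alt_codon = (
        ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1 :]
    )
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "truncating"
    return "missense"


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
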