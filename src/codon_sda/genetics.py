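"""Standard genetic-code helpers shared across the toolkit.

Everything is keyed on DNA alphabet codons/anticodons (A, C, G, T).  The
codon table is NCBI translation table 1 (the standard nuclear code);
six-fold degenerate amino acids (Leu, Ser, Arg) are treated as single
synonymous families.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

#: all 64 codons, in TCAG-within-box order (third base cycles T, C, A, G)
ALL_CODONS: list[str] = [
    n1 + n2 + n3 for n1 in "TCAG" for n2 in "TCAG" for n3 in "TCAG"
]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in box order
SENSE_CODONS: list[str] = [c for c in ALL_CODONS if c not in STOP_CODONS]

#: sense codon -> one-letter amino acid
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

#: one-letter amino acid -> synonymous codon family (box order preserved)
AA_TO_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], []).append(_c)

AA_THREE_LETTER: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
THREE_TO_ONE: dict[str, str] = {v: k for k, v in AA_THREE_LETTER.items()}

#: labels tRNAscan-SE may emit that are not ordinary cytosolic amino acids
SPECIAL_AA_LABELS: frozenset[str] = frozenset({"SeC", "Sup", "Und", "iMet"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercased)."""
    return str(Seq(seq.upper()).reverse_complement())


def anticodon_to_codon(anticodon: str) -> str:
    """Cognate (Watson-Crick) codon of an anticodon: its reverse complement."""
    return revcomp(anticodon)


def codon_to_anticodon(codon: str) -> str:
    """Watson-Crick anticodon decoding a codon: its reverse complement."""
    return revcomp(codon)


#: all 64 anticodons (reverse complements of ALL_CODONS)
ALL_ANTICODONS: list[str] = [codon_to_anticodon(c) for c in ALL_CODONS]

#: anticodons whose cognate codon is a stop (e.g. TCA decodes TGA)
STOP_COGNATE_ANTICODONS: frozenset[str] = frozenset(
    codon_to_anticodon(c) for c in STOP_CODONS
)

#: anticodon -> amino-acid family of its cognate codon (stop cognates absent)
ANTICODON_TO_AA: dict[str, str] = {
    a: CODON_TO_AA[anticodon_to_codon(a)]
    for a in ALL_ANTICODONS
    if a not in STOP_COGNATE_ANTICODONS
}

#: amino acid -> anticodons decoding its synonymous codons
AA_TO_ANTICODONS: dict[str, list[str]] = {}
for _a, _aa in ANTICODON_TO_AA.items():
    AA_TO_ANTICODONS.setdefault(_aa, []).append(_a)


def is_valid_anticodon(anticodon: str) -> bool:
    return len(anticodon) == 3 and all(b in NUCLEOTIDES for b in anticodon)
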