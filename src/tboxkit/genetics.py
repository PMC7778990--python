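"""Genetic-code helpers shared across the toolkit.

All sequences handled here are RNA strings over {A, C, G, U, N}. The standard
genetic code (NCBI translation table 1) is taken from Biopython; triplets that
cannot be translated (ambiguity codes, non-bases) map to the undetermined
marker ``"X"`` and stop codons map to ``"*"``.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq1

RNA_BASES = frozenset("ACGU")
RNA_ALPHABET = frozenset("ACGUN")

#: marker for a triplet whose amino-acid family cannot be determined
UNDETERMINED = "X"

_TABLE = CodonTable.unambiguous_rna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: Watson-Crick base pairs plus the G:U wobble, as unordered pairs.
WATSON_CRICK = frozenset({frozenset("AU"), frozenset("GC")})
WOBBLE = frozenset({frozenset("GU")})
PAIRABLE = WATSON_CRICK | WOBBLE


def normalize_rna(sequence: str) -> str:
    """Upper-case and convert DNA-style T to U. Idempotent."""
    return sequence.upper().replace("T", "U")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(sequence: str) -> str:
    """Reverse complement of an RNA string (N self-complements)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def aa_from_codon(triplet: str) -> str:
    """Translate a codon-like triplet to a one-letter amino-acid code.

    Returns ``"*"`` for stop codons and :data:`UNDETERMINED` for triplets
    containing N or any non-RNA character.
    """
    if len(triplet) != 3 or not set(triplet) <= RNA_BASES:
        return UNDETERMINED
    if triplet in _STOPS:
        return "*"
    return _TABLE.forward_table[triplet]


def family_from_3letter(name: str) -> str:
    """One-letter family from a three-letter code ('Trp' -> 'W').

    Unrecognized names (e.g. 'Undet', 'Sup') return :data:`UNDETERMINED`.
    """
    one = seq1(name.capitalize())
    return one if one in set("ACDEFGHIKLMNPQRSTVWY") else UNDETERMINED


def can_pair(x: str, y: str, wobble: bool = True) -> bool:
    """True iff x:y is a Watson-Crick pair, or a G:U wobble when allowed."""
    pair = frozenset((x, y))
    if pair in WATSON_CRICK:
        return True
    return wobble and pair in WOBBLE


#: one-letter code -> aminoacyl-tRNA synthetase name, used for default
#: downstream-gene annotations and the ontology keyword table
SYNTHETASE_NAMES = {
    "A": "alanyl-tRNA synthetase",
    "R": "arginyl-tRNA synthetase",
    "N": "asparaginyl-tRNA synthetase",
    "D": "aspartyl-tRNA synthetase",
    "C": "cysteinyl-tRNA synthetase",
    "Q": "glutaminyl-tRNA synthetase",
    "E": "glutamyl-tRNA synthetase",
    "G": "glycyl-tRNA synthetase",
    "H": "histidyl-tRNA synthetase",
    "I": "isoleucyl-tRNA synthetase",
    "L": "leucyl-tRNA synthetase",
    "K": "lysyl-tRNA synthetase",
    "M": "methionyl-tRNA synthetase",
    "F": "phenylalanyl-tRNA synthetase",
    "P": "prolyl-tRNA synthetase",
    "S": "seryl-tRNA synthetase",
    "T": "threonyl-tRNA synthetase",
    "W": "tryptophanyl-tRNA synthetase",
    "Y": "tyrosyl-tRNA synthetase",
    "V": "valyl-tRNA synthetase",
}

#: all sense codons of a family, keyed by one-letter code ('*' = stops)
CODONS_BY_FAMILY: dict[str, tuple[str, ...]] = {}
for _b1 in "ACGU":
    for _b2 in "ACGU":
        for _b3 in "ACGU":
            _c = _b1 + _b2 + _b3
            CODONS_BY_FAMILY.setdefault(aa_from_codon(_c), tuple())
            CODONS_BY_FAMILY[aa_from_codon(_c)] += (_c,)
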