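"""Frozen specifier -> amino-acid family assignment for all 64 triplets,
as printed in published specifier-usage tables (standard genetic code)."""

SPEC_TO_AA = {
    "AAA": "K", "AGA": "R", "ACA": "T", "AUA": "I",
    "AAG": "K", "AGG": "R", "ACG": "T", "AUG": "M",
    "AAC": "N", "AGC": "S", "ACC": "T", "AUC": "I",
    "AAU": "N", "AGU": "S", "ACU": "T", "AUU": "I",
    "GAA": "E", "GGA": "G", "GCA": "A", "GUA": "V",
    "GAG": "E", "GGG": "G", "GCG": "A", "GUG": "V",
    "GAC": "D", "GGC": "G", "GCC": "A", "GUC": "V",
    "GAU": "D", "GGU": "G", "GCU": "A", "GUU": "V",
    "CAA": "Q", "CGA": "R", "CCA": "P", "CUA": "L",
    "CAG": "Q", "CGG": "R", "CCG": "P", "CUG": "L",
    "CAC": "H", "CGC": "R", "CCC": "P", "CUC": "L",
    "CAU": "H", "CGU": "R", "CCU": "P", "CUU": "L",
    "UAA": "*", "UGA": "*", "UCA": "S", "UUA": "L",
    "UAG": "*", "UGG": "W", "UCG": "S", "UUG": "L",
    "UAC": "Y", "UGC": "C", "UCC": "S", "UUC": "F",
    "UAU": "Y", "UGU": "C", "UCU": "S", "UUU": "F",
}
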