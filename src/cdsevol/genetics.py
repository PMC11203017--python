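"""Shared genetic-code constants (standard nuclear code).

All tables are derived from Biopython's standard codon table at import time,
so every module in the package works from the same code.
"""
from __future__ import annotations

from Bio.Data import CodonTable

_STD = CodonTable.unambiguous_dna_by_id[1]

BASES = ("A", "C", "G", "T")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: codon -> one-letter amino acid, 61 sense codons only
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (sorted)
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYN_FAMILIES.setdefault(_aa, ())
    SYN_FAMILIES[_aa] = SYN_FAMILIES[_aa] + (_codon,)

#: amino acid -> degeneracy (family size)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in SYN_FAMILIES.items()}

#: Wright's degeneracy classes: class size -> amino acids
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _d in sorted(DEGENERACY.items()):
    if _d > 1:
        DEGENERACY_CLASSES.setdefault(_d, ())
        DEGENERACY_CLASSES[_d] = DEGENERACY_CLASSES[_d] + (_aa,)

#: the 59 codons informative for synonymous usage (Met/Trp excluded)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)


def is_transition(base_a: str, base_b: str) -> bool:
    """True if the base change is a transition (purine<->purine or pyr<->pyr)."""
    if base_a == base_b:
        raise ValueError("identical bases are not a change")
    return (base_a in PURINES) == (base_b in PURINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; 'X' if the codon contains N."""
    if "N" in codon:
        return "X"
    return CODON_TO_AA[codon]
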