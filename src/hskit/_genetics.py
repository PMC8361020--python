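"""Shared genetic-code helpers (standard code, T-alphabet)."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: codon -> one-letter amino acid; stop codons map to "*"
CODON_TO_AA: dict[str, str] = {
    **standard_dna_table.forward_table,
    **{c: "*" for c in STOP_CODONS},
}

#: amino acid -> tuple of codons, in fixed codon-table order
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

#: the two-fold degenerate amino acids (third-position transitions only)
TWOFOLD_AAS: frozenset[str] = frozenset(
    aa for aa, cs in AA_TO_CODONS.items() if aa != "*" and len(cs) == 2
)


def synonymous(codon_a: str, codon_b: str) -> bool:
    """True if two codons encode the same amino acid under the standard code."""
    return CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b]


def normalize_codon(codon: str) -> str:
    """Upper-case and convert RNA (U) to DNA (T)."""
    return codon.upper().replace("U", "T")
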