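"""Codon-usage tables and synonymous substitution maps.

Codon-usage bias is tabulated as frequencies per thousand codons
(Kazusa-style tables). For two-fold degenerate amino acids the two
synonymous codons differ only at the third position; the less frequent one
is *under-represented* and the more frequent one *over-represented* in a
given host. Replacing every under-represented codon by its over-represented
synonym yields a host-specific substitution map that preserves the protein
while shifting the coding sequence toward the host's codon preferences
(and, for A/T-ending under-represented codons, raising GC content).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from ._genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    CODONS,
    STOP_CODONS,
    normalize_codon,
)

logger = logging.getLogger(__name__)

#: the eight two-fold degenerate amino acids optimized by default
DEFAULT_AA_SET = "CEFHKNQY"

#: species shipped as packaged frequency tables (eight amino acids each)
PACKAGED_SPECIES = (
    "physcomitrium_patens",
    "spodoptera_frugiperda",
    "homo_sapiens",
    "cricetulus_griseus",
    "oryza_sativa",
    "nicotiana_tabacum",
)


class CodonTableError(ValueError):
    """Malformed or incomplete codon-usage table."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-species codon frequencies per thousand, T-alphabet keys."""

    species_label: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.freq)
        extra = set(self.freq) - set(CODONS)
        if missing or extra:
            raise CodonTableError(
                f"table must have exactly the 64 codons; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        bad = [c for c, f in self.freq.items() if f < 0]
        if bad:
            raise CodonTableError(f"negative frequency for {sorted(bad)}")

    @classmethod
    def from_partial(
        cls, species_label: str, freq: dict[str, float]
    ) -> "CodonUsageTable":
        """Build a table from a codon subset, zero-filling absent codons.

        Intended for the packaged per-amino-acid fixture tables; classifying
        an amino acid whose codons are all zero raises.
        """
        full = {c: 0.0 for c in CODONS}
        for codon, f in freq.items():
            full[normalize_codon(codon)] = float(f)
        return cls(species_label, full)


@dataclass(frozen=True)
class TwoCodonBias:
    """Under/over-represented codon pair for a two-fold degenerate amino acid."""

    amino_acid: str
    under_codon: str
    over_codon: str
    under_freq: float
    over_freq: float

    def __post_init__(self) -> None:
        if CODON_TO_AA[self.under_codon] != self.amino_acid:
            raise ValueError(f"{self.under_codon} does not encode {self.amino_acid}")
        if CODON_TO_AA[self.over_codon] != self.amino_acid:
            raise ValueError(f"{self.over_codon} does not encode {self.amino_acid}")
        if self.over_freq < self.under_freq:
            raise ValueError("over_freq must be >= under_freq")


@dataclass(frozen=True)
class SubstitutionMap:
    """Synonymous source->target codon replacement rules."""

    rules: dict[str, str]
    origin_species: str = ""

    def __post_init__(self) -> None:
        for src, tgt in self.rules.items():
            if CODON_TO_AA[src] != CODON_TO_AA[tgt]:
                raise ValueError(f"rule {src}->{tgt} is not synonymous")
            if src in STOP_CODONS or tgt in STOP_CODONS:
                raise ValueError(f"rule {src}->{tgt} involves a stop codon")
        overlap = set(self.rules.values()) & set(self.rules)
        if overlap:
            raise ValueError(f"target codons also appear as sources: {sorted(overlap)}")

    def to_json(self) -> str:
        return json.dumps(self.rules, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, origin_species: str = "") -> "SubstitutionMap":
        return cls(dict(json.loads(text)), origin_species)


# Kazusa layouts: bracketed "codon freq (count)" fields, possibly several per
# line, or plain two-column "codon freq" lines.
_KAZUSA_FIELD = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)(?:\s*\(\s*[0-9]+\s*\))?"
)


def parse_usage_table(text: str, species_label: str = "") -> CodonUsageTable:
    """Parse Kazusa-style codon-usage text into a :class:`CodonUsageTable`.

    Accepts both the bracketed ``codon freq (count)`` layout and plain
    two-column lines; U and T alphabets are both accepted and normalized to
    T. All 64 codons must appear exactly once.
    """
    freq: dict[str, float] = {}
    for m in _KAZUSA_FIELD.finditer(text):
        codon = normalize_codon(m.group(1))
        if codon in freq:
            raise CodonTableError(f"duplicated codon {codon}")
        freq[codon] = float(m.group(2))
    missing = set(CODONS) - set(freq)
    if missing:
        raise CodonTableError(f"missing codon(s): {', '.join(sorted(missing))}")
    return CodonUsageTable(species_label, freq)


def write_usage_table(table: CodonUsageTable) -> str:
    """Serialize a table as plain two-column text (round-trips with the parser)."""
    lines = [f"{c} {table.freq[c]}" for c in CODONS]
    return "\n".join(lines) + "\n"


def load_species_table(species: str) -> CodonUsageTable:
    """Load one of the packaged per-species frequency tables.

    The packaged tables carry only the two codons for each of the eight
    two-fold degenerate amino acids optimized by default; other codons are
    zero-filled.
    """
    if species not in PACKAGED_SPECIES:
        raise KeyError(
            f"unknown species {species!r}; available: {', '.join(PACKAGED_SPECIES)}"
        )
    ref = importlib.resources.files("hskit.data") / f"{species}.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    return CodonUsageTable.from_partial(
        species, dict(zip(df["codon"], df["freq_per_thousand"]))
    )


def _check_aa_set(aa_set: str) -> list[str]:
    aas = list(aa_set)
    for aa in aas:
        codons = AA_TO_CODONS.get(aa)
        if codons is None or aa == "*":
            raise ValueError(f"unknown amino acid {aa!r}")
        if len(codons) != 2:
            raise ValueError(
                f"amino acid {aa} has {len(codons)} codons; "
                "only two-fold degenerate amino acids are supported"
            )
    return aas


def classify_two_codon_bias(
    table: CodonUsageTable, aa_set: str = DEFAULT_AA_SET
) -> list[TwoCodonBias]:
    """Classify under/over-represented codons for two-fold degenerate amino acids.

    Ties (equal frequencies) produce no record and are logged as a warning:
    with no usage bias there is no rationale for substituting.
    """
    out: list[TwoCodonBias] = []
    for aa in _check_aa_set(aa_set):
        c1, c2 = AA_TO_CODONS[aa]
        f1, f2 = table.freq[c1], table.freq[c2]
        if f1 == f2:
            logger.warning(
                "%s: tie for %s (%s=%s, %s=%s); no bias record",
                table.species_label, aa, c1, f1, c2, f2,
            )
            continue
        (under, fu), (over, fo) = sorted(
            [(c1, f1), (c2, f2)], key=lambda p: p[1]
        )
        out.append(TwoCodonBias(aa, under, over, fu, fo))
    return out


def derive_substitution_map(
    table: CodonUsageTable, aa_set: str = DEFAULT_AA_SET
) -> SubstitutionMap:
    """Derive the under->over codon substitution map for a host table."""
    biases = classify_two_codon_bias(table, aa_set)
    return SubstitutionMap(
        {b.under_codon: b.over_codon for b in biases}, table.species_label
    )


def compare_bias_across_species(
    reference: CodonUsageTable,
    others: list[CodonUsageTable],
    aa_set: str = DEFAULT_AA_SET,
) -> pd.DataFrame:
    """Count, per species, amino acids whose preferred codon matches the reference.

    Returns a DataFrame with one row per species: ``species``, ``agreement``
    (count of amino acids whose over-represented codon equals the
    reference's), ``n_compared`` and ``matching_aas``.
    """
    ref = {b.amino_acid: b.over_codon for b in classify_two_codon_bias(reference, aa_set)}
    rows = []
    for other in others:
        over = {
            b.amino_acid: b.over_codon
            for b in classify_two_codon_bias(other, aa_set)
        }
        matches = sorted(aa for aa in ref if over.get(aa) == ref[aa])
        rows.append(
            {
                "species": other.species_label,
                "agreement": len(matches),
                "n_compared": len(ref),
                "matching_aas": "".join(matches),
            }
        )
    return pd.DataFrame(rows, columns=["species", "agreement", "n_compared", "matching_aas"])
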