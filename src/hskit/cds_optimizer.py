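"""CDS validation, codon-wise optimization and splice-motif ablation.

A heterologous CDS is optimized for a host by replacing every
under-represented two-fold codon with its over-represented synonym
(:mod:`hskit.codon_usage`). Because all eight default rules are T->C or
A->G at the third position, optimization strictly raises GC content
whenever it changes anything, while the encoded protein is untouched.

Splice-motif ablation is the complementary surgical operation: given
cryptic-intron candidates detected in the CDS, it destroys the donor
(exonic ``AG`` | intronic ``GT``) or acceptor (intronic ``AG``) core with
the fewest possible synonymous codon edits, so the motif no longer matches
but the protein is unchanged. Candidates whose core is pinned by Met/Trp
(single-codon amino acids) or stop codons may be unresolvable; those are
reported, never silently dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetics import AA_TO_CODONS, CODON_TO_AA, STOP_CODONS
from .codon_usage import CodonUsageTable, SubstitutionMap

if TYPE_CHECKING:  # pragma: no cover
    from .cryptic_scanner import CrypticIntron

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")


class CdsError(ValueError):
    """Structurally unusable CDS input."""


@dataclass(frozen=True)
class CdsRecord:
    """A named coding sequence over {A,C,G,T,N}, upper-cased on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise CdsError(f"{self.id}: empty sequence")
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise CdsError(f"{self.id}: invalid characters {sorted(bad)}")

    def translate(self) -> str:
        """Standard-code translation of the full sequence (stops as '*')."""
        n = len(self.seq) - len(self.seq) % 3
        return str(Seq(self.seq[:n]).translate())


@dataclass
class ValidationReport:
    length_ok: bool
    start_ok: bool
    stop_ok: bool
    internal_stop_codons: list[int]
    warnings: list[str]

    @property
    def all_ok(self) -> bool:
        return (
            self.length_ok
            and self.start_ok
            and self.stop_ok
            and not self.internal_stop_codons
        )


@dataclass
class OptimizationReport:
    n_codons: int
    n_changed: int
    changed_positions: list[int]
    gc_before: float
    gc_after: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class AblationEdit:
    """One synonymous codon replacement made to destroy a splice core."""

    codon_index: int
    before: str
    after: str


@dataclass
class AblationReport:
    resolved: list[tuple["CrypticIntron", list[AblationEdit]]]
    unresolvable: list["CrypticIntron"]
    warnings: list[str] = field(default_factory=list)


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N excluded from both counts."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise CdsError("sequence has no A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / acgt


def validate_cds(record: CdsRecord) -> ValidationReport:
    """Check length, start, stop and internal stop codons.

    All failures are warnings, never hard errors: a CDS that fails a check
    is still processable (matching physCO behavior).
    """
    warnings: list[str] = []
    length_ok = len(record.seq) % 3 == 0
    if not length_ok:
        warnings.append(
            f"{record.id}: length {len(record.seq)} not divisible by 3"
        )
    codons = [record.seq[i : i + 3] for i in range(0, len(record.seq) - 2, 3)]
    start_ok = bool(codons) and codons[0] == "ATG"
    if not start_ok:
        warnings.append(f"{record.id}: first codon is not ATG")
    stop_ok = length_ok and bool(codons) and codons[-1] in STOP_CODONS
    if not stop_ok:
        warnings.append(f"{record.id}: last codon is not a stop codon")
    internal = [
        i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS
    ]
    for i in internal:
        warnings.append(f"{record.id}: internal stop codon at codon index {i}")
    return ValidationReport(length_ok, start_ok, stop_ok, internal, warnings)


def optimize_cds(
    record: CdsRecord, submap: SubstitutionMap
) -> tuple[CdsRecord, OptimizationReport]:
    """Apply a synonymous substitution map codon-wise.

    Codons containing N are skipped with a warning. The translation of the
    output equals that of the input by the map's synonymy invariant.
    """
    if len(record.seq) % 3 != 0:
        raise CdsError(
            f"{record.id}: length {len(record.seq)} not divisible by 3"
        )
    gc_before = gc_content(record.seq)
    warnings: list[str] = []
    out: list[str] = []
    changed: list[int] = []
    for i in range(0, len(record.seq), 3):
        codon = record.seq[i : i + 3]
        if "N" in codon:
            warnings.append(
                f"{record.id}: codon {i // 3} contains N; left untouched"
            )
            out.append(codon)
            continue
        new = submap.rules.get(codon, codon)
        if new != codon:
            changed.append(i // 3)
        out.append(new)
    new_seq = "".join(out)
    new_record = CdsRecord(record.id, new_seq)
    assert new_record.translate() == record.translate()
    report = OptimizationReport(
        n_codons=len(out),
        n_changed=len(changed),
        changed_positions=changed,
        gc_before=gc_before,
        gc_after=gc_content(new_seq),
        warnings=warnings,
    )
    return new_record, report


def _synonymous_alternatives(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid, the codon itself included."""
    return AA_TO_CODONS[CODON_TO_AA[codon]]


def _attack_targets(
    intron: "CrypticIntron", cds: str, sides: tuple[str, ...] = ("donor", "acceptor")
) -> list[tuple[range, str]]:
    """Dinucleotide targets whose loss defuses the candidate intron.

    Removing the intronic ``GT`` (donor), the exonic ``AG`` immediately
    upstream of it (when present — it completes the ``AG|GT`` core), or the
    intronic ``AG`` (acceptor) each suffices.
    """
    d = intron.donor.junction_pos
    a = intron.acceptor.junction_pos
    targets = []
    if "donor" in sides:
        targets.append((range(d, d + 2), "GT"))
        if d >= 2 and cds[d - 2 : d] == "AG":
            targets.append((range(d - 2, d), "AG"))
    if "acceptor" in sides:
        targets.append((range(a - 2, a), "AG"))
    return [
        (rng, motif)
        for rng, motif in targets
        if rng.start >= 0 and rng.stop <= len(cds)
    ]


def ablate_splice_motifs(
    record: CdsRecord,
    candidates: Iterable["CrypticIntron"],
    table: CodonUsageTable,
    sides: tuple[str, ...] = ("donor", "acceptor"),
) -> tuple[CdsRecord, AblationReport]:
    """Destroy candidate splice cores with minimal synonymous codon edits.

    For each candidate the donor core (``AG|GT``) and the acceptor core
    (``AG``) are attacked independently; an edit set is accepted only if it
    destroys the core while leaving the translation unchanged. Among minimal
    edit sets, replacements that are themselves under-represented source
    codons of the host's substitution map are avoided when possible (a
    subsequent codon optimization would revert them and could resurrect the
    motif), then the highest summed usage frequency under *table* wins.
    Candidates with no synonymous escape are reported as unresolvable.
    *sides* restricts which cores are attacked (e.g. ``("donor",)`` to
    leave the acceptor untouched).
    """
    from .codon_usage import derive_substitution_map

    sources = frozenset(derive_substitution_map(table).rules)
    seq = list(record.seq)
    report = AblationReport(resolved=[], unresolvable=[])
    for intron in candidates:
        d, a = intron.donor.junction_pos, intron.acceptor.junction_pos
        if not (0 <= d <= len(seq)) or not (0 < a <= len(seq)):
            raise CdsError(
                f"candidate intron [{d}, {a}) outside CDS of length {len(seq)}"
            )
        edits = _ablate_one(seq, intron, table, sides, sources)
        if edits is None:
            report.unresolvable.append(intron)
            logger.warning(
                "%s: candidate intron [%d, %d) has no synonymous ablation",
                record.id, d, a,
            )
        else:
            for e in edits:
                seq[e.codon_index * 3 : e.codon_index * 3 + 3] = e.after
            report.resolved.append((intron, edits))
    new_record = CdsRecord(record.id, "".join(seq))
    assert new_record.translate() == record.translate()
    return new_record, report


def _ablate_one(
    seq: list[str],
    intron: "CrypticIntron",
    table: CodonUsageTable,
    sides: tuple[str, ...] = ("donor", "acceptor"),
    avoid: frozenset[str] = frozenset(),
) -> list[AblationEdit] | None:
    """Minimal synonymous edit set defusing one candidate intron.

    Enumerates synonymous replacements of the codons overlapping each attack
    target (at most two codons per dinucleotide target); prefers fewer edits,
    then higher summed usage frequency of the replacement codons.
    """
    cds = "".join(seq)
    if len(cds) % 3:
        raise CdsError("ablation requires a CDS with length divisible by 3")
    targets = _attack_targets(intron, cds, sides)
    for rng, motif in targets:
        if cds[rng.start : rng.stop] != motif:
            return []  # a shared core was already destroyed earlier
    best: list[AblationEdit] | None = None
    best_key: tuple = ()
    for rng, motif in targets:
        touched = sorted({p // 3 for p in rng})
        for n_edits in range(1, len(touched) + 1):
            for combo in itertools.combinations(touched, n_edits):
                originals = [cds[i * 3 : i * 3 + 3] for i in combo]
                for repl in itertools.product(
                    *(_synonymous_alternatives(c) for c in originals)
                ):
                    if any(r == o for r, o in zip(repl, originals)):
                        continue
                    trial = list(cds)
                    for idx, codon in zip(combo, repl):
                        trial[idx * 3 : idx * 3 + 3] = codon
                    if "".join(trial)[rng.start : rng.stop] == motif:
                        continue  # target survived
                    # fewest edits, then fewest map-source codons, then
                    # highest summed usage frequency
                    key = (
                        -n_edits,
                        -sum(c in avoid for c in repl),
                        sum(table.freq[c] for c in repl),
                    )
                    edits = [
                        AblationEdit(i, o, r)
                        for i, o, r in zip(combo, originals, repl)
                    ]
                    if best is None or key > best_key:
                        best, best_key = edits, key
    return best


def harden_cds(
    record: CdsRecord,
    table: CodonUsageTable,
    donor_pwm,
    acceptor_pwm,
    min_score: float | None = None,
    min_intron_len: int = 50,
):
    """Full hardening pipeline: optimize, then iterated scan -> ablate.

    Codon optimization runs first (raising GC and settling every codon the
    substitution map touches); scan-and-ablate rounds then repeat until no
    candidate intron scores above threshold or no further synonymous edit
    is possible. Ablation avoids under-represented codons, so the result
    is a fixed point of both steps. Any introns still above threshold at
    the end (unresolvable cores) are reported as residual, never hidden.

    Returns ``(hardened_record, HardeningReport)`` carrying the
    optimization report, the per-round ablation reports and the residual
    introns.
    """
    from dataclasses import dataclass as _dc

    from .codon_usage import derive_substitution_map
    from .cryptic_scanner import enumerate_cryptic_introns, scan_candidates

    @_dc
    class HardeningReport:
        optimization: OptimizationReport
        ablation_rounds: list[AblationReport]
        residual: list

    def _introns(seq: str):
        cands = scan_candidates(seq, donor_pwm, acceptor_pwm, min_score=min_score)
        return enumerate_cryptic_introns(seq, cands, cands, min_len=min_intron_len)

    current, opt_report = optimize_cds(record, derive_substitution_map(table))
    rounds: list[AblationReport] = []
    for _ in range(8):
        introns = _introns(current.seq)
        if not introns:
            break
        ablated, rep = ablate_splice_motifs(current, introns, table)
        rounds.append(rep)
        if ablated.seq == current.seq:  # only unresolvable candidates left
            break
        current = ablated
    return current, HardeningReport(opt_report, rounds, _introns(current.seq))


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a (possibly multi-record) FASTA file into CdsRecords."""
    return [CdsRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write CdsRecords as FASTA, sequence lines wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")
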