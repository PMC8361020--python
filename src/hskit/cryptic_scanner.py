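"""Cryptic splice-site detection and in-silico splicing of a CDS.

A heterologous CDS expressed in a splicing-competent host can be
mis-recognized as a pre-mRNA: any internal ``GT`` can act as a donor and
any ``AG`` as an acceptor, provided the surrounding 18-base context
resembles the host's splice-site consensus. This module scores every
GT/AG-anchored context against position weight matrices derived from the
host's splice atlas (log-odds, bits, vs a uniform background), pairs
donors with downstream acceptors into candidate GT-AG introns, splices
them out in silico, and characterizes the resulting transcript variants:
reading frame, premature termination codons, average protein mass, and the
junction-spanning tryptic peptides by which a spliced isoform would be
recognized in mass spectrometry.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from pyteomics import mass as _pyteomics_mass

from .cds_optimizer import gc_content
from .splice_atlas import _BASE_INDEX, PositionFrequencyMatrix, log_odds_pwm

logger = logging.getLogger(__name__)

WATER_MASS_DA = 18.02


@dataclass(frozen=True)
class SpliceSiteCandidate:
    """A GT (donor) or AG (acceptor) core with its context log-odds score.

    ``junction_pos`` is the 0-based CDS offset of the exon/intron boundary:
    for donors the intron would start at ``junction_pos`` (so the CDS reads
    ``GT`` there); for acceptors the intron would end at ``junction_pos``
    (so the CDS reads ``AG`` at ``junction_pos - 2``).
    """

    kind: str
    junction_pos: int
    score: float
    core: str


@dataclass(frozen=True)
class CrypticIntron:
    """A candidate GT-AG intron inside a CDS, half-open [donor, acceptor)."""

    donor: SpliceSiteCandidate
    acceptor: SpliceSiteCandidate
    length: int
    gc: float
    frame_preserving: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.donor.junction_pos, self.acceptor.junction_pos)

    @property
    def combined_score(self) -> float:
        return self.donor.score + self.acceptor.score


@dataclass
class SpliceVariantModel:
    """A spliced transcript variant and the protein it implies."""

    variant_seq: str
    protein: str  # translation up to (excluding) the first stop codon
    has_ptc: bool
    mass_da: float
    frame_preserving: bool
    junction_codon_index: int | None = None
    deleted_aa: int | None = None
    junction_positions_nt: tuple[int, ...] = ()

    @property
    def mass_kda(self) -> float:
        return round(self.mass_da / 1000.0, 1)


def default_min_score(pwm: np.ndarray, margin: float = 6.0) -> float:
    """Score of the consensus context under *pwm*, minus *margin* bits."""
    return float(pwm.max(axis=0).sum()) - margin


def _context_score(context: str, pwm: np.ndarray) -> float | None:
    if len(context) != pwm.shape[1] or "N" in context:
        return None
    return float(sum(pwm[_BASE_INDEX[b], j] for j, b in enumerate(context)))


def scan_candidates(
    cds: str,
    donor_pwm: np.ndarray | PositionFrequencyMatrix,
    acceptor_pwm: np.ndarray | PositionFrequencyMatrix,
    min_score: float | None = None,
    half_window: int = 9,
) -> list[SpliceSiteCandidate]:
    """Find GT/AG cores whose 18-base context scores above threshold.

    PFMs are accepted and converted to log-odds PWMs (+1 pseudocount).
    ``min_score=None`` uses each PWM's consensus score minus 6 bits; pass a
    number to override (the same threshold is applied to both kinds).
    Returns candidates of both kinds sorted by position.
    """
    if isinstance(donor_pwm, PositionFrequencyMatrix):
        donor_pwm = log_odds_pwm(donor_pwm)
    if isinstance(acceptor_pwm, PositionFrequencyMatrix):
        acceptor_pwm = log_odds_pwm(acceptor_pwm)
    cds = cds.upper()
    if len(cds) < 2 * half_window:
        logger.warning("CDS shorter than the scoring window; no candidates")
        return []
    out: list[SpliceSiteCandidate] = []
    for kind, pwm in (("donor", donor_pwm), ("acceptor", acceptor_pwm)):
        threshold = default_min_score(pwm) if min_score is None else min_score
        core_re = "GT" if kind == "donor" else "AG"
        for m in re.finditer(core_re, cds):
            # junction: donors sit 5' of the GT, acceptors 3' of the AG
            junction = m.start() if kind == "donor" else m.end()
            context = cds[junction - half_window : junction + half_window]
            if junction - half_window < 0:
                continue
            score = _context_score(context, pwm)
            if score is not None and score >= threshold:
                out.append(SpliceSiteCandidate(kind, junction, score, core_re))
    out.sort(key=lambda c: (c.junction_pos, c.kind))
    return out


def enumerate_cryptic_introns(
    cds: str,
    donors: Iterable[SpliceSiteCandidate],
    acceptors: Iterable[SpliceSiteCandidate],
    min_len: int = 50,
    max_len: int | None = None,
    max_gc: float | None = None,
) -> list[CrypticIntron]:
    """All (donor, downstream acceptor) pairs within the length/GC bounds.

    Sorted by combined log-odds score, best first. *donors*/*acceptors* may
    be mixed candidate lists; they are filtered by kind.
    """
    cds = cds.upper()
    donors = [c for c in donors if c.kind == "donor"]
    acceptors = [c for c in acceptors if c.kind == "acceptor"]
    out: list[CrypticIntron] = []
    for d in donors:
        for a in acceptors:
            length = a.junction_pos - d.junction_pos
            if length < max(min_len, 1):
                continue
            if max_len is not None and length > max_len:
                continue
            gc = gc_content(cds[d.junction_pos : a.junction_pos])
            if max_gc is not None and gc > max_gc:
                continue
            out.append(
                CrypticIntron(
                    donor=d,
                    acceptor=a,
                    length=length,
                    gc=gc,
                    frame_preserving=length % 3 == 0,
                )
            )
    out.sort(key=lambda i: -i.combined_score)
    return out


def splice_out(cds: str, introns: Sequence[CrypticIntron]) -> str:
    """Remove non-overlapping introns from a CDS; returns the spliced variant."""
    ivs = sorted(i.interval for i in introns)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping introns [{s1},{e1}) and [{s2},{e2})")
    pieces = []
    pos = 0
    for s, e in ivs:
        pieces.append(cds[pos:s])
        pos = e
    pieces.append(cds[pos:])
    return "".join(pieces)


def characterize_variant(
    variant_seq: str,
    cds: str,
    introns: Sequence[CrypticIntron] = (),
) -> SpliceVariantModel:
    """Translate a spliced variant and report frame, PTC and protein mass.

    Translation uses the standard code and stops at the first stop codon;
    the mass is the average molecular mass of that (possibly truncated)
    product. With the removed *introns* supplied, the splice-junction
    positions in variant coordinates are recorded and, for frame-preserving
    variants, the codon index of the first junction and the number of
    deleted residues.
    """
    if len(variant_seq) < 3:
        raise ValueError("variant shorter than one codon")
    removed = len(cds) - len(variant_seq)
    frame_preserving = removed % 3 == 0
    n = len(variant_seq) - len(variant_seq) % 3
    full = str(Seq(variant_seq[:n]).translate())
    has_ptc = "*" in full[:-1]
    protein = full.split("*")[0]
    junctions: list[int] = []
    shift = 0
    for iv in sorted(i.interval for i in introns):
        junctions.append(iv[0] - shift)
        shift += iv[1] - iv[0]
    model = SpliceVariantModel(
        variant_seq=variant_seq,
        protein=protein,
        has_ptc=has_ptc,
        mass_da=protein_mass(protein) if protein else 0.0,
        frame_preserving=frame_preserving,
        junction_positions_nt=tuple(junctions),
    )
    if frame_preserving and introns:
        model.junction_codon_index = junctions[0] // 3
        model.deleted_aa = removed // 3
    return model


_STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def protein_mass(protein: str) -> float:
    """Average (not monoisotopic) molecular mass of a protein, in Daltons."""
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - _STANDARD_AAS
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return float(_pyteomics_mass.calculate_mass(sequence=protein, average=True))


_TRYPSIN_CUT = re.compile(r"(?<=[KR])(?!P)")


def digest_trypsin(protein: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic peptides: cleave after K or R except before P.

    With ``missed_cleavages=0`` the peptides concatenate back to the input
    in order. With ``missed_cleavages=k`` every run of up to k+1 consecutive
    fully-cleaved peptides is also emitted (standard missed-cleavage
    expansion), ordered by start position then length.
    """
    if not protein:
        return []
    base = [p for p in _TRYPSIN_CUT.split(protein) if p]
    if missed_cleavages == 0:
        return base
    out = []
    for i in range(len(base)):
        for k in range(min(missed_cleavages + 1, len(base) - i)):
            out.append("".join(base[i : i + k + 1]))
    return out


def junction_peptides(
    variant: SpliceVariantModel, peptides: Iterable[str]
) -> list[str]:
    """Peptides containing at least one residue from each side of a junction.

    Peptides are located in the variant's translated protein; a peptide
    straddles a junction at nucleotide offset j if it covers coding
    positions both below and above j. A junction falling exactly at a
    cleavage boundary is straddled by no peptide. Only defined for
    frame-preserving variants.
    """
    if not variant.frame_preserving:
        raise ValueError("junction peptides are undefined for frameshifted variants")
    protein = variant.protein
    out: list[str] = []
    for pep in peptides:
        start = protein.find(pep)
        if start < 0:
            continue
        for j in variant.junction_positions_nt:
            if start * 3 < j < (start + len(pep)) * 3:
                out.append(pep)
                break
    return out
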