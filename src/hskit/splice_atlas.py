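"""Genome-wide splice-site profiling.

Every annotated intron contributes two 18-base windows centred on its
junctions: a donor window (9 exonic + 9 intronic bases) and an acceptor
window (9 intronic + 9 exonic bases), both written 5'->3' on the transcript
strand, so that positions 10-11 of a donor window read the intron's first
two bases (canonically ``GT``) and positions 8-9 of an acceptor window read
its last two (``AG``). Position frequency matrices over these windows give
the host's splice-site consensus; the fraction of windows carrying the
``CAG|GT`` junction 5-mer measures how dominant that motif is among real
splice sites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed annotation or genome/annotation mismatch."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons as 0-based half-open genomic intervals.

    ``exons`` are stored in transcript 5'->3' order: ascending genomic
    coordinates on the plus strand, descending on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            if s2 - e1 < 1:
                raise AnnotationError(f"{self.transcript_id}: zero-length intron")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals in transcript 5'->3' order."""
        genomic = sorted(self.exons)
        gaps = tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(genomic, genomic[1:])
        )
        return gaps if self.strand == "+" else gaps[::-1]


@dataclass(frozen=True)
class SpliceWindow:
    """An 18-base junction window on the transcript strand.

    The junction lies between indices 8 and 9 (``junction_offset`` bases of
    exon precede it for donors / of intron for acceptors).
    """

    kind: str  # "donor" | "acceptor"
    window: str
    transcript_id: str
    junction_offset: int = 9

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"bad window kind {self.kind!r}")
        if len(self.window) != 2 * self.junction_offset:
            raise ValueError(
                f"window length {len(self.window)} != {2 * self.junction_offset}"
            )


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over a set of equal-length windows."""

    kind: str
    counts: np.ndarray  # (4, window length), rows A,C,G,T
    n_windows: int
    n_skipped: int = 0  # windows excluded for containing N

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A,C,G,T)")
        colsums = self.counts.sum(axis=0)
        if self.n_windows and not np.all(colsums == self.n_windows):
            raise ValueError("every column must sum to n_windows")

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_windows

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "n_windows": self.n_windows,
                "n_skipped": self.n_skipped,
                "counts": {b: self.counts[i].tolist() for i, b in enumerate(BASES)},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PositionFrequencyMatrix":
        d = json.loads(text)
        counts = np.array([d["counts"][b] for b in BASES])
        return cls(d["kind"], counts, d["n_windows"], d.get("n_skipped", 0))


# ---------------------------------------------------------------------------
# genome access: plain dicts (tests, fixtures) or pyfaidx.Fasta both work


def _contig_seq(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        return str(genome[chrom])
    try:
        return str(genome[chrom][:])
    except KeyError as exc:
        raise AnnotationError(f"unknown chromosome {chrom!r}") from exc


def load_genome(path: str | Path) -> Mapping[str, str]:
    """Load a genome FASTA into a chrom -> sequence mapping (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3 parsing

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def load_transcript_models(
    annotation: str | Path, genome: Mapping[str, str] | None = None
) -> list[TranscriptModel]:
    """Load transcript models from a GFF3 file.

    One model per mRNA/transcript feature; exons are attached through their
    ``Parent`` attribute. Features of other biotypes are ignored (their
    count is logged). If *genome* is given, exons referencing chromosomes
    absent from it raise.
    """
    import gffutils

    path = str(annotation)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    n_other = 0
    for feat in db.all_features():
        if feat.featuretype == "exon":
            continue
        if feat.featuretype not in _TRANSCRIPT_TYPES:
            if feat.featuretype != "gene":
                n_other += 1
            continue
        exons = sorted(
            (e.start - 1, e.end)  # GFF3 1-based inclusive -> 0-based half-open
            for e in db.children(feat, featuretype="exon")
        )
        if not exons:
            continue
        if genome is not None and feat.seqid not in genome:
            raise AnnotationError(
                f"{feat.id}: exon references unknown chromosome {feat.seqid!r}"
            )
        parents = list(db.parents(feat, featuretype="gene"))
        gene_id = parents[0].id if parents else feat.id
        if feat.strand == "-":
            exons = exons[::-1]
        models.append(
            TranscriptModel(
                transcript_id=feat.id,
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=tuple(exons),
            )
        )
    if n_other:
        logger.info("ignored %d features of non-mRNA biotypes", n_other)
    return models


def _prevalidate_gff3(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_cols = len(line.split("\t"))
            if n_cols != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed GFF3 line ({n_cols} columns)"
                )


# ---------------------------------------------------------------------------
# window extraction and summarization


def extract_splice_windows(
    models: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    half_window: int = 9,
    dedupe_introns: bool = False,
    gtag_only: bool = False,
) -> list[SpliceWindow]:
    """Extract donor and acceptor windows around every annotated intron.

    Minus-strand windows are reverse-complemented so they read 5'->3' on the
    transcript. Junctions with less than *half_window* flank at a contig
    edge are skipped with a warning. With ``dedupe_introns`` each distinct
    genomic intron contributes once regardless of how many isoforms share
    it; with ``gtag_only`` introns not starting GT / ending AG are dropped.
    """
    windows: list[SpliceWindow] = []
    seen: set[tuple] = set()
    for model in models:
        contig = _contig_seq(genome, model.chrom)
        for g0, g1 in model.introns:
            if gtag_only:
                intron_seq = contig[g0:g1]
                if model.strand == "-":
                    intron_seq = reverse_complement(intron_seq)
                if not (intron_seq[:2] == "GT" and intron_seq[-2:] == "AG"):
                    continue
            key = (model.chrom, model.strand, g0, g1)
            if dedupe_introns:
                if key in seen:
                    continue
                seen.add(key)
            if g0 - half_window < 0 or g1 + half_window > len(contig):
                logger.warning(
                    "%s: junction at %s:%d-%d too close to contig edge; skipped",
                    model.transcript_id, model.chrom, g0, g1,
                )
                continue
            lo = contig[g0 - half_window : g0 + half_window]
            hi = contig[g1 - half_window : g1 + half_window]
            if model.strand == "+":
                donor, acceptor = lo, hi
            else:
                donor, acceptor = reverse_complement(hi), reverse_complement(lo)
            windows.append(SpliceWindow("donor", donor, model.transcript_id, half_window))
            windows.append(
                SpliceWindow("acceptor", acceptor, model.transcript_id, half_window)
            )
    return windows


def build_pfm(windows: list[SpliceWindow]) -> PositionFrequencyMatrix:
    """Tally per-position base counts; windows containing N are excluded."""
    if not windows:
        raise ValueError("cannot build a PFM from zero windows")
    kinds = {w.kind for w in windows}
    lengths = {len(w.window) for w in windows}
    if len(kinds) > 1 or len(lengths) > 1:
        raise ValueError("all windows must share kind and length")
    (kind,) = kinds
    (width,) = lengths
    counts = np.zeros((4, width), dtype=np.int64)
    n_used = n_skipped = 0
    for w in windows:
        if "N" in w.window:
            n_skipped += 1
            continue
        for j, base in enumerate(w.window):
            counts[_BASE_INDEX[base], j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("all windows contained N")
    return PositionFrequencyMatrix(kind, counts, n_used, n_skipped)


def junction_motif_fraction(
    windows: list[SpliceWindow], motif: str = "CAGGT", anchor: int = -3
) -> float:
    """Fraction of windows matching *motif* anchored relative to the junction.

    The default (``CAGGT`` at anchor -3) places ``CAG`` as the last three
    bases before the junction and ``GT`` as the first two after it: for
    donor windows that is the last 3 exonic + first 2 intronic bases; for
    acceptor windows the last 3 intronic + first 2 exonic bases. Windows
    containing N are excluded from the denominator.
    """
    if not windows:
        raise ValueError("no windows")
    usable = [w for w in windows if "N" not in w.window]
    if not usable:
        raise ValueError("all windows contained N")
    n_match = 0
    for w in usable:
        start = w.junction_offset + anchor
        if start < 0 or start + len(motif) > len(w.window):
            raise ValueError(
                f"motif {motif!r} at anchor {anchor} does not fit the window"
            )
        if w.window[start : start + len(motif)] == motif:
            n_match += 1
    return n_match / len(usable)


def logo_matrix(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Information-content letter heights (bits), shape (4, width).

    Per column: height(base) = p(base) * (2 - H(column)), H the Shannon
    entropy in bits. No small-sample correction is applied.
    """
    if pfm.n_windows < 1:
        raise ValueError("PFM is empty")
    p = pfm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=0)
    return p * (2.0 - entropy)


def log_odds_pwm(
    pfm: PositionFrequencyMatrix, pseudocount: float = 1.0, background: float = 0.25
) -> np.ndarray:
    """Log-odds scoring matrix (bits) vs a uniform background.

    A pseudocount is added to every PFM cell before normalization, so the
    PWM is finite even for bases never observed at a position.
    """
    smoothed = pfm.counts + pseudocount
    p = smoothed / smoothed.sum(axis=0, keepdims=True)
    return np.log2(p / background)


def consensus_window(pfm: PositionFrequencyMatrix) -> str:
    """Most frequent base at each position (ties: first of A,C,G,T)."""
    return "".join(BASES[i] for i in pfm.counts.argmax(axis=0))


def windows_to_tsv(windows: Iterable[SpliceWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\ttranscript_id\twindow\n")
        for w in windows:
            fh.write(f"{w.kind}\t{w.transcript_id}\t{w.window}\n")
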