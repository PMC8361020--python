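"""Deterministic synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of its arguments including the seed, so
regeneration is byte-identical. Three substrates are produced:

* toy genomes with annotated multi-exon genes whose introns all follow the
  GT-AG rule and where an exact, chosen fraction of donors carries the
  ``CAG|GT`` junction 5-mer (both strands), for the splice atlas;
* valid ORFs with one planted cryptic GT-AG intron of controlled length
  and GC content, for the scanner and the hardening pipeline;
* 3-D intensity stacks with a known foreground mask and mean, for the
  quantification pipeline.

Exonic background composition defaults to 50% GC (typical of the moss
host's coding sequence), intronic background to 30% GC (plant introns are
A/T-rich).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._genetics import STOP_CODONS
from .splice_atlas import reverse_complement

EXON_GC = 0.50
INTRON_GC = 0.30


@dataclass
class FixtureTruth:
    """Planted ground truth of one generated fixture, plus the seed used."""

    kind: str
    seed: int
    items: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)

        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "items": self.items},
            default=_default,
            sort_keys=True,
        )


def _check_seed(seed) -> int:
    if seed is None:
        raise ValueError("a concrete integer seed is required (reproducibility)")
    return int(seed)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_nonstop_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    out = []
    while len(out) < n:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# toy genome


def make_toy_genome(
    n_genes: int = 50,
    introns_per_gene: int = 3,
    donor_caggt_fraction: float = 0.23,
    seed: int = 0,
    exon_len: int = 60,
    intron_len: int = 90,
    spacer_len: int = 50,
) -> tuple[dict[str, str], str, FixtureTruth]:
    """Generate an annotated toy genome on one chromosome.

    All introns start ``GT`` and end ``AG``; exactly
    ``round(donor_caggt_fraction * n_donors)`` donor junctions read
    ``CAG|GT`` and every other donor is guaranteed not to. Genes alternate
    between the two strands. Returns ``(genome, gff3_text, truth)`` with
    the genome as a chrom -> sequence mapping.
    """
    seed = _check_seed(seed)
    if not 0 <= donor_caggt_fraction <= 1:
        raise ValueError("donor_caggt_fraction must lie in [0, 1]")
    if exon_len < 10 or intron_len < 5:
        raise ValueError("exon/intron lengths too short for +-9 bp windows")
    rng = np.random.default_rng(seed)
    n_donors = n_genes * introns_per_gene
    n_caggt = round(donor_caggt_fraction * n_donors)
    caggt_flags = np.zeros(n_donors, dtype=bool)
    caggt_flags[rng.choice(n_donors, size=n_caggt, replace=False)] = True

    chrom_parts: list[str] = []
    gff_lines = ["##gff-version 3"]
    truth_genes = []
    offset = 0
    donor_idx = 0
    chrom = "chr1"
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        chrom_parts.append(_random_bases(rng, spacer_len, 0.5))
        offset += spacer_len
        # build the gene block in transcript orientation
        block_parts: list[str] = []
        exon_ivs: list[tuple[int, int]] = []  # transcript-oriented, block-local
        pos = 0
        gene_donors = []
        for e in range(introns_per_gene + 1):
            exon = _random_bases(rng, exon_len, EXON_GC)
            if e < introns_per_gene:
                if caggt_flags[donor_idx]:
                    exon = exon[:-3] + "CAG"
                else:
                    while exon.endswith("CAG"):
                        exon = exon[:-3] + _random_bases(rng, 3, EXON_GC)
                gene_donors.append(bool(caggt_flags[donor_idx]))
                donor_idx += 1
            block_parts.append(exon)
            exon_ivs.append((pos, pos + exon_len))
            pos += exon_len
            if e < introns_per_gene:
                intron = (
                    "GT"
                    + _random_bases(rng, intron_len - 4, INTRON_GC)
                    + "AG"
                )
                block_parts.append(intron)
                pos += intron_len
        block = "".join(block_parts)
        if strand == "-":
            genome_block = reverse_complement(block)
            ivs = [(len(block) - e, len(block) - s) for s, e in exon_ivs]
        else:
            genome_block = block
            ivs = exon_ivs
        chrom_parts.append(genome_block)
        gene_start, gene_end = offset, offset + len(block)
        gid, tid = f"gene{g}", f"gene{g}.t1"
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{chrom}\ttoy\tmRNA\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        for s, e in sorted(ivs):
            gff_lines.append(
                f"{chrom}\ttoy\texon\t{offset + s + 1}\t{offset + e}\t.\t{strand}\t.\t"
                f"Parent={tid}"
            )
        truth_genes.append(
            {"gene_id": gid, "strand": strand, "donor_caggt": gene_donors}
        )
        offset += len(block)
    chrom_parts.append(_random_bases(rng, spacer_len, 0.5))
    genome = {chrom: "".join(chrom_parts)}
    truth = FixtureTruth(
        "toy_genome",
        seed,
        {
            "n_genes": n_genes,
            "introns_per_gene": introns_per_gene,
            "n_donors": n_donors,
            "n_caggt_donors": int(n_caggt),
            "donor_caggt_fraction": n_caggt / n_donors if n_donors else 0.0,
            "genes": truth_genes,
        },
    )
    return genome, "\n".join(gff_lines) + "\n", truth


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS with a planted cryptic intron


def make_cds_with_cryptic_intron(
    cds_len: int = 900,
    intron_len: int = 132,
    intron_gc: float = 0.39,
    donor_context: str | None = None,
    acceptor_context: str | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[str, FixtureTruth]:
    """Generate a valid ORF containing one planted cryptic GT-AG intron.

    The planted donor reads ``CAG|GT`` at a codon boundary and the intron
    ends ``...CAG|``; the intron's GC content lands within +-2% of
    *intron_gc*. Optional *donor_context*/*acceptor_context* (the 9
    intronic bases at each junction, e.g. a genome-consensus half-window)
    strengthen the planted sites; the donor context must start ``GT`` and
    the acceptor context end ``AG``.
    """
    seed = _check_seed(seed)
    if cds_len % 3:
        raise ValueError("cds_len must be divisible by 3")
    if not intron_len < cds_len - 6:
        raise ValueError("intron_len must be < cds_len - 6")
    donor_in = donor_context if donor_context is not None else "GTAAGTTTA"
    acceptor_in = acceptor_context if acceptor_context is not None else "TTTTTGCAG"
    if not donor_in.startswith("GT") or len(donor_in) != 9:
        raise ValueError("donor_context must be 9 bases starting GT")
    if not acceptor_in.endswith("AG") or len(acceptor_in) != 9:
        raise ValueError("acceptor_context must be 9 bases ending AG")
    acceptor_in = acceptor_in[:-3] + "CAG"  # the planted acceptor reads ...CAG|
    # codon-aligned donor, centred intron; >=12 nt flanks for scan windows
    d = 3 * ((cds_len - intron_len) // 6)
    d = max(d - d % 3, 12)
    a = d + intron_len
    if a > cds_len - 12:
        raise ValueError("intron does not fit with 12 nt flanks")

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        codons = ["ATG"]
        codons.append(_random_nonstop_codons(rng, cds_len // 3 - 2, EXON_GC))
        codons.append("TAA")
        cds = list("".join(codons))
        cds[d - 3 : d] = "CAG"  # exonic Gln completing the CAG|GT donor core
        cds[d : d + 9] = donor_in
        cds[a - 9 : a] = acceptor_in
        interior_gc = _solve_interior_gc(
            rng, cds, d, a, intron_gc, donor_in, acceptor_in
        )
        if interior_gc is None:
            continue
        # only the CAG|GT and ...CAG cores are sacrosanct; stop-codon repair
        # may touch other context bases (contexts can contain in-frame stops)
        _repair_internal_stops(cds, protected=set(range(d - 3, d + 2)) | set(range(a - 3, a)))
        seq = "".join(cds)
        gc = _gc(seq[d:a])
        if abs(gc - intron_gc) <= 0.02 and _is_clean_orf(seq):
            truth = FixtureTruth(
                "cryptic_cds",
                seed,
                {
                    "donor_pos": d,
                    "acceptor_pos": a,
                    "intron_len": intron_len,
                    "intron_gc": gc,
                    "frame_preserving": intron_len % 3 == 0,
                    "deleted_aa": intron_len // 3 if intron_len % 3 == 0 else None,
                },
            )
            return seq, truth
    raise ValueError(
        f"could not hit intron GC {intron_gc:.2f} +-2% in {max_tries} tries"
    )


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _solve_interior_gc(rng, cds, d, a, target, donor_in, acceptor_in):
    """Resample the intron interior (between the context 9-mers) toward a GC target."""
    lo, hi = d + 9, a - 9
    if hi <= lo:
        return _gc("".join(cds[d:a]))
    fixed_gc = sum(c in "GC" for c in donor_in + acceptor_in)
    need = target * (a - d) - fixed_gc
    interior_target = min(max(need / (hi - lo), 0.02), 0.98)
    cds[lo:hi] = _random_bases(rng, hi - lo, interior_target)
    gc = _gc("".join(cds[d:a]))
    return gc if abs(gc - target) <= 0.02 else None


def _repair_internal_stops(cds: list[str], protected: set[int]) -> None:
    """Mutate one unprotected base of every internal in-frame stop codon."""
    for _ in range(10):
        dirty = False
        for i in range(0, len(cds) - 3, 3):
            codon = "".join(cds[i : i + 3])
            if codon in STOP_CODONS:
                for p in range(i, i + 3):
                    if p not in protected:
                        cds[p] = "C"  # any single C substitution kills a stop
                        dirty = True
                        break
        if not dirty:
            return


def _is_clean_orf(seq: str) -> bool:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return (
        codons[0] == "ATG"
        and codons[-1] in STOP_CODONS
        and not any(c in STOP_CODONS for c in codons[:-1])
    )


# ---------------------------------------------------------------------------
# synthetic 3-D stacks


def make_synthetic_stack(
    shape: tuple[int, int, int] = (24, 48, 48),
    pattern: str = "cube",
    fg_mean: float = 100.0,
    noise_sd: float = 0.0,
    gradient_amp: float = 0.0,
    bg_mean: float = 0.0,
    seed: int = 0,
):
    """Generate a 3-D stack with known foreground geometry and mean.

    Patterns: ``cube`` (one solid block, a compact organelle-like signal),
    ``diffuse`` (scattered dilated blobs, mislocalized signal) and
    ``network`` (axis-aligned filaments, ER-like tubular signal). Gaussian
    noise of *noise_sd* is added everywhere and a linear intensity gradient
    of amplitude *gradient_amp* along X on top; values are clipped at 0.
    Returns ``(VoxelStack, FixtureTruth)``; the truth carries the planted
    mask and the realized foreground mean.
    """
    from .stack_quant import VoxelStack

    seed = _check_seed(seed)
    if fg_mean <= bg_mean:
        raise ValueError("fg_mean must exceed the background mean")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    if pattern == "cube":
        cz, cy, cx = nz // 3, ny // 3, nx // 3
        mask[
            (nz - cz) // 2 : (nz + cz) // 2,
            (ny - cy) // 2 : (ny + cy) // 2,
            (nx - cx) // 2 : (nx + cx) // 2,
        ] = True
    elif pattern == "diffuse":
        n_blobs = max(5, int(mask.size * 0.001))
        pts = rng.integers([3, 3, 3], [nz - 3, ny - 3, nx - 3], size=(n_blobs, 3))
        for z, y, x in pts:
            mask[z - 2 : z + 3, y - 2 : y + 3, x - 2 : x + 3] = True
    elif pattern == "network":
        for _ in range(max(6, nz // 3)):
            axis = rng.integers(0, 3)
            z, y, x = (rng.integers(2, n - 2) for n in shape)
            sl = [slice(z, z + 1), slice(y, y + 1), slice(x, x + 1)]
            sl[axis] = slice(None)
            mask[tuple(sl)] = True
        from scipy import ndimage as _ndi

        # tubules ~5 voxels across, comparable to ER strands at 80 nm voxels
        mask = _ndi.binary_dilation(mask, iterations=2)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    values = np.full(shape, float(bg_mean))
    values[mask] = fg_mean
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=shape)
    if gradient_amp > 0:
        values = values + gradient_amp * np.linspace(0, 1, nx)[None, None, :]
    values = np.clip(values, 0.0, None)
    truth = FixtureTruth(
        "synthetic_stack",
        seed,
        {
            "pattern": pattern,
            "fg_mean": fg_mean,
            "noise_sd": noise_sd,
            "gradient_amp": gradient_amp,
            "true_foreground_mean": float(values[mask].mean()),
            "n_foreground": int(mask.sum()),
            "mask": mask,
        },
    )
    return VoxelStack(values), truth
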