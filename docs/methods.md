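# Methods

`hskit` addresses *heterosplicing*: a coding sequence (CDS) transplanted
from one organism into a splicing-competent host can be mis-read as a
pre-mRNA, so that the host spliceosome excises "cryptic introns" from what
should be an intronless transcript. The result is a population of shortened
mRNAs and fragmentary, mislocalized protein isoforms, and a corresponding
loss of full-length product. The package implements the computational side
of diagnosing and preventing this in the moss *Physcomitrium patens* (and,
by extension, any host with a similar splice-site grammar): codon-usage
analysis and synonymous optimization, genome-wide splice-site profiling,
cryptic-intron prediction with in-silico splicing, and quantification of
reporter fluorescence in 3-D confocal stacks.

## Codon-usage model (`codon_usage`)

Codon usage is taken as Kazusa-style frequencies per thousand codons. For a
two-fold degenerate amino acid the two synonymous codons differ only at the
third (wobble) position; whichever is rarer in the host is
*under-represented*. The substitution map sends each under-represented
codon to its over-represented partner for the eight two-fold amino acids
Cys, Glu, Phe, His, Lys, Asn, Gln, Tyr (Asp, also two-fold, is accepted on
request but excluded from the default set). In the moss all eight rules are
T→C or A→G at the wobble position, so applying the map strictly raises GC
content whenever it changes anything — the mechanistic point, since plant
introns are A/T-rich and GC content is one signal separating exon from
intron.

Design choices:

* **Ties** (equal frequencies) produce no rule and a logged warning: with
  no bias there is no rationale for substituting.
* RNA-alphabet input (U) is normalized to DNA (T) at the parser boundary.
* The packaged per-species tables (moss, *S. frugiperda*, human, Chinese
  hamster, rice, tobacco) carry only the sixteen codons of the default
  eight amino acids; absent codons are zero-filled via an explicit
  constructor, and classifying an amino acid with no data raises.

Cross-species comparison counts, per species, the amino acids whose
preferred codon matches the reference host's. On the packaged tables the
moss agrees with rice, human, CHO and *S. frugiperda* on 8/8 amino acids
and with tobacco on 1/8 (Lys only) — the basis for expecting the same
optimization recipe to transfer to those production systems but not to
*Nicotiana*.

## CDS optimization and splice-motif ablation (`cds_optimizer`)

Validation checks length divisibility, ATG start, terminal stop and
internal stop codons, and reports warnings rather than failing: only a
length not divisible by three blocks optimization. Optimization applies the
substitution map codon-wise; codons containing N are skipped with a
warning; the translation is asserted unchanged.

Ablation destroys a candidate intron with the fewest synonymous codon
edits. Each candidate exposes up to three dinucleotide attack targets: the
intronic `GT` (donor), the exonic `AG` directly upstream when present (it
completes the `AG|GT` core), and the intronic `AG` (acceptor); destroying
any one defuses the candidate. The search enumerates all synonymous
replacements of the (at most two) codons overlapping a target and ranks
edit sets by (fewest edits, fewest codons that are themselves
under-represented map sources, highest summed usage frequency). The middle
criterion exists because a subsequent codon optimization would revert a
source codon and could resurrect the motif. Candidates with no synonymous
escape — e.g. a `GT` spanning two Trp codons, when only the donor side may
be edited — are reported as unresolvable, never dropped.

`harden_cds` chains the steps: optimize first (settling every codon the
map touches), then scan-and-ablate rounds until no candidate intron scores
above threshold or no edit is possible, then a final scan whose surviving
introns are reported as residual. Optimize-first plus the source-avoidance
rule makes the result a fixed point of both steps (verified by the
idempotence tests).

## Splice-site atlas (`splice_atlas`)

Transcript models come from GFF3 (exons attached to mRNA/transcript
features; other biotypes counted and ignored; GFF3's 1-based inclusive
coordinates converted to 0-based half-open at the parser boundary only).
Every intron yields two 18-base windows written 5′→3′ on the transcript
strand: a donor window (9 exonic + 9 intronic bases) and an acceptor
window (9 intronic + 9 exonic), so a canonical donor reads `GT` at columns
10–11 and an acceptor `AG` at columns 8–9. Minus-strand windows are
reverse-complemented; junctions with insufficient flank at a contig edge
are skipped with a warning.

Windows feed three summaries:

* a **position frequency matrix** (4×18 counts; windows containing N are
  excluded but tallied), whose columns each sum to the window count;
* the **junction-motif fraction**, by default the `CAG|GT` 5-mer anchored
  3 bases before the junction — for donors the last 3 exonic plus first 2
  intronic bases, for acceptors the last 3 intronic plus first 2 exonic;
* a **logo matrix** of information-content letter heights,
  `p · (2 − H(column))` bits with no small-sample correction (rendering is
  out of scope; the matrix is the deliverable).

Introns are counted once per transcript that contains them; because
published fractions may instead deduplicate introns shared between
isoforms, or restrict to canonical GT-AG introns, both behaviours are
available (`dedupe_introns`, `gtag_only`) and both interpretations are
checked wherever a reference fraction is compared.

For scanning, the PFM is converted to a log-odds position weight matrix in
bits against a uniform 0.25 background with +1 pseudocount per cell.

## Cryptic-intron scanner (`cryptic_scanner`)

Every `GT` (potential donor) and `AG` (potential acceptor) in a CDS is
scored by summing the PWM over its 18-base context; sites at the sequence
edge (incomplete context) are ignored. The default threshold is the PWM's
consensus score minus 6 bits — a deliberately permissive margin, tunable,
since no published cutoff exists for this host. Donor–acceptor pairs with
the acceptor downstream and a length of at least 50 nt (all experimentally
recovered cryptic introns in the motivating system exceeded 120 nt;
50 keeps the bound permissive while excluding micro-deletions) become
candidate introns, optionally filtered by maximum length and GC content,
sorted by combined score.

Splicing removes non-overlapping introns and concatenates the retained
segments. Variant characterization translates with the standard code,
stops at the first stop codon, flags a premature termination codon when a
stop precedes the final codon, and computes the **average** (not
monoisotopic) molecular mass of the truncated product via standard average
residue masses — matching how isoform masses are reported at kDa
precision. Junction bookkeeping records each splice point in variant
coordinates; for frame-preserving variants the deleted-residue count is
the removed length over three.

Tryptic digestion cleaves C-terminal of K or R except before P (the plain
rule, without the rare WKP/MRP sub-exceptions some engines add); with k
missed cleavages every run of up to k+1 consecutive fully-cleaved peptides
is emitted. A peptide is *junction-spanning* when it covers coding
positions on both sides of a splice point — the mass-spectrometric
signature of a spliced isoform; a junction exactly at a cleavage boundary
is spanned by nothing.

## 3-D stack quantification (`stack_quant`)

The pipeline reproduces a five-step confocal quantification protocol.
Defaults (all tunable, axis order Z,Y,X; voxel size 0.300 × 0.080 ×
0.080 µm):

1. **median filter**, window (3,3,3) — salt-and-pepper removal;
2. **unsharp mask**, `out = in + amount·(in − gaussian(in, σ))` clipped at
   0, σ = 1.0 voxel and amount = 1.0 (the original protocol does not state
   them; both are exposed);
3. **Richardson–Lucy restoration**, 3 iterations, uniform (3,5,5)
   averaging PSF — smoothing that preserves thin structures. Implemented
   directly as the multiplicative update with *reflective* boundaries, so
   a constant stack is a fixed point (an FFT implementation with zero
   padding would erode the borders);
4. **local intensity equalization**: the stack is tiled into (7,7,7)
   boxes; a box with meaningfully positive sample skewness gets weight
   `clamp(median_skew / skew, 0.5, 2.0)`, damping boxes with an unusually
   heavy bright tail and boosting weak ones. Near-symmetric boxes (skew ≤
   10⁻⁶) and stacks whose median skewness is not positive keep weight 1 —
   the ratio is undefined there, and rescaling single-class boxes only
   injects noise (sample skewness is invariant under affine intensity
   changes, so this step equalizes tail *shape*, not additive gradients).
   Weights are tri-linearly interpolated between box centres before
   multiplication to avoid block artifacts. The exact weight rule in the
   original home-built code is unpublished; this rule is this package's
   design, exposed as the defaults of `equalize_local`, and reported group
   means can shift under a different rule;
5. **adaptive Otsu segmentation**: Otsu thresholds on non-overlapping
   (7,19,19) tiles, tri-linearly interpolated to voxel resolution (a
   sliding per-voxel variant exists behind a flag and is exact but far
   slower). A tile lying entirely on one side of the whole-stack Otsu
   threshold holds a single intensity class — Otsu would split that class
   in half — so such tiles inherit the global threshold. A voxel is
   foreground iff it exceeds both its local threshold and 0.66 × the
   global threshold (the low global floor suppresses over-segmentation of
   noisy background).

The reported quantity is the mean of the **original, unprocessed** voxel
values under the mask; the processed copy exists only to build the mask.
An empty mask reports mean 0 with a warning. Integer input is promoted to
float at entry. Groups of stacks processed with identical parameters are
compared by two-group one-way fixed-effects ANOVA (for two groups, F = t²
of the pooled t-test).

## Synthetic fixtures (`fixtures`)

All generators are pure functions of their arguments including the
mandatory integer seed; regeneration is byte-identical.

* **Toy genomes**: multi-exon genes alternating between strands on one
  chromosome; exonic background 50% GC (the host's average coding GC),
  intronic background 30% GC (plant introns are A/T-rich); every intron
  GT…AG; exactly `round(fraction · n_donors)` donors carry the `CAG|GT`
  junction 5-mer and every other donor is guaranteed not to, so the atlas
  must recover the planted fraction exactly.
* **Cryptic-intron CDSs**: valid ORFs with one planted intron whose donor
  reads `CAG|GT` at a codon boundary and whose acceptor ends `…CAG|`;
  intron GC lands within ±2% of target (default 0.39, the GC range of
  cryptic introns observed in a human CDS expressed in moss). Optional
  donor/acceptor context 9-mers (e.g. the toy genome's consensus) let the
  planted site outrank background sites. Only the `CAG|GT` and `…CAG`
  cores are sacrosanct: if a supplied context would introduce an in-frame
  stop codon, the repair pass may alter context bases outside the cores.
* **Stacks**: `cube` (compact block), `diffuse` (scattered 5³ blobs —
  mislocalized signal) and `network` (dilated axis-aligned filaments,
  ~5 voxels across — ER-like tubules at 80 nm voxels) on a flat
  background, plus Gaussian noise and an optional linear gradient, clipped
  at 0; the truth records the planted mask and realized foreground mean.

What the fixtures do **not** emulate: realistic moss gene architecture
(isoform structure, repeat content, branch points, polypyrimidine tracts),
sequencing/annotation noise, optical PSF anisotropy, photon (Poisson)
noise, bleaching, or spectral cross-talk. Passing tests therefore
demonstrate algorithmic correctness under controlled conditions, not
performance on real micrographs or a real genome.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small inputs:
toy genomes of 40–50 genes (120–200 introns), 900 nt CDSs, and
24 × 48 × 48 stacks with three replicates per group — large enough for the
planted-truth recoveries to be exact or tightly banded, small enough that
the whole suite completes in seconds. Randomized property tests
(1,000-case optimizer and splicing loops) use fixed seeds. Boundary
handling is reflective everywhere; ties in consensus calls resolve to the
first base in A,C,G,T order; all reported masses are average-isotopic,
rounded to 0.1 kDa at the reporting boundary only.

## Known limitations

* The scanner scores sites independently; it does not model branch points,
  polypyrimidine tracts, exon/intron definition or any cooperative or
  quantitative splicing-efficiency effects, and the log-odds threshold is
  a heuristic.
* The equalization weight rule is a design choice (see above); published
  group means from other implementations need not reproduce exactly.
* Tiled Otsu with interpolation can misplace the boundary by a voxel or
  two around structures much smaller than a tile; the sliding variant
  avoids this at substantial cost.
* Three reference comparisons (a human factor H construct, and the moss
  v3.3 genome release) require inputs that cannot be redistributed; the
  corresponding tests fail with instructions unless the files are placed
  under `data/external/` (see the README there).
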