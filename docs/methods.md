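# Methods

This note records the models, conventions and design choices behind
mhcforge, in the order a user meets them.

## Coordinates and alignments

All internal coordinates are 0-based half-open; 1-based formats (GFF3,
RepeatMasker .out, VCF) are converted at the I/O boundary, and the
conversions are involutive. Alignments use the extended CIGAR alphabet
`=XID`, where `I` consumes query and `D` consumes target, matching
SAM/PAF conventions. Minus-strand records store their CIGAR against the
reverse-complemented query walked in ascending target order, the same
convention minimap2 uses; query coordinates always refer to the original
strand.

`global_align` is an exact Gotoh affine-gap DP (gap of length L costs
`gap_open + L·gap_extend`; defaults 1/−1/−2/−1). It stores full traceback
matrices, so it is intended for inputs up to a few tens of kbp; larger
alignments enter through PAF. `N` never counts as a match. Tie-breaking is
deterministic: match/mismatch preferred over query insertion over
deletion, and gap runs extend rather than reopen, which left-normalizes
indel runs. The test suite checks score-level agreement with an
independent plain-Python DP on hundreds of random pairs.

Semi-global placement searches (HLA typing, gene placement, C4 anchors)
use edlib, a unit-cost aligner with free end gaps on the target side.
Where contiguity of large gap runs matters (C4 below), unit-cost optima
are ambiguous and the run structure is rebuilt from anchored sub-alignments.

## Once-only projection and variant counting

To quantify polymorphism of an assembly (query) against a reference, all
alignment records are projected onto the reference starting with the
longest (target-span ties: more matches, then lower start coordinate — the
result is invariant to input order). Each query base is projected at most
once, even under overlapping supplementary/secondary alignments; on the
reference side the first writer wins. Insertion events are recorded only
when all their query bases are unused, deletion events only when all their
reference slots are empty.

From the projection: a SNP is a projected position whose query and
reference bases differ (both in `ACGT`); insertion/deletion events shorter
than the SV floor (default 1000 bp) are INDELs; events of at least the
floor, and never-projected stretches of *more than* 1000 bp on either
sequence, are SVs. The classes are disjoint, and the ≥/> asymmetry between
the two SV criteria is intentional (the event rule is inclusive at
1000 bp; the uncovered-stretch rule is strict). Windowed densities use
1 kbp non-overlapping windows with events assigned by reference start
coordinate; the final partial window is kept. Inversions are not treated
separately here: minus-strand records project as covered sequence.

## HLA typing

Every genomic allele of the database is placed on the assembly on both
strands with free end gaps on the assembly side, and the allele minimizing
the unit-cost edit distance of its best placement wins. Unit-cost
Levenshtein is the simplest defensible metric for "closest match" and
yields small integer distances suitable for reporting. Ties prefer
complete alleles (those whose row spans the full locus MSA without unknown
characters; any `*`/`.` column makes an allele incomplete), then the
lowest name in natural field order. A locus is called absent when even the
best allele's placement costs more than 20 % of the allele length — this
threshold only needs to separate "gene present" (distance near 0) from
"gene absent" (distance ~50 % of length for random sequence), and
anything in that wide corridor behaves identically; absence of DRB3/4/5 is
what drives DR-group classification. When the best allele is incomplete,
the full locus sequence is extracted using the placement of the closest
*complete* allele, and the incomplete allele can be completed from the
extraction provided its known span matches exactly (a mismatch would make
the completion chimeric and is an error).

## Gene annotation

Reference gene models come from a three-tier source set with precedence
allele-database > curated-genomic > fallback. A gene is annotated only if
some alignment covers its reference sequence entirely; the highest-scoring
such alignment (ties: identity, then lower coordinate) fixes the gene
interval. The built-in placement provider trims terminal indel runs (as a
local aligner would clip) and drops alignments below 90 % identity, so
heavily disrupted copies yield no complete placement rather than a
misleading one. Exon boundaries are mapped through the CIGAR; a boundary
falling inside an assembly-relative insertion snaps to the leftmost valid
assembly coordinate, consistent with VCF-style left normalization.
Transcripts are checked for translational consistency: ATG start, stop
codon end, no in-frame internal stop (CDS length not a multiple of 3 is
"rejected"). Failing transcripts are suppressed except for genes on a
caller-supplied exception list of loci known to encode incomplete
products; pseudogene models skip the check entirely.

## C4 genotyping

C4 copies are found by locating the two HERV-flanking segments of a
HERV-carrying C4A reference independently on both strands (each within
10 % of its length in edit distance), chaining adjacent, correctly
oriented and spaced pairs into copies, and globally aligning the full
reference against each chained span part-by-part. This mirrors
seed-and-chain alignment and is necessary because a single unit-cost
placement of the whole reference would price a genuine HERV-less copy
(one ~19 kb deletion in the real gene) as badly as random sequence, and
because tied-cost tracebacks scatter such a deletion across the CIGAR.
Per copy: HERV status is S iff the alignment contains a deletion of at
least `deletion_floor` (default 5000 bp — far above ordinary intron
indels, far below the insertion) overlapping the HERV interval; the
isotype is read from the translated exon-26 peptide (`PCPVLD` → A,
`LSPVIH` → B; neither, or an unprojectable exon 26, → unclassified, with
HERV status still reported). The exon-26 reading frame is a property of
the reference exon table, not re-derived per assembly. Genotypes are
comma-joined haplotype-order labels (`AL`, `BS`, ...); unclassified
isotypes appear as `?` and flag the genotype.

## Polishing rules

Three independent operators, each idempotent:

1. *Homozygous variant substitution*: only `hom` calls are applied, right
   to left, so printed VCF coordinates need no lift-over; a REF mismatch
   is an error. Heterozygous calls are skipped.
2. *Contig substitution*: a contig alignment qualifies when query cover ×
   identity ≥ 0.99 (inclusive). Qualifying contigs are applied in
   descending quality; one overlapping an already-substituted interval is
   skipped and logged, making the result order-independent.
3. *Majority polishing*: a base changes only when the modal alleles of
   both technologies agree, each is a strict majority (> 50 %) of its
   column depth, the allele is a single base, and it differs from the
   assembly. Exactly 50 % is not a majority. Depth-0 columns and
   single-technology columns never change; sequence length is preserved.
   The iteration count of the outer polishing loop is a CLI parameter by
   design — convergence was historically judged by inspection.

## Structure comparison

A haplotype MSA provides the common coordinate system; per-haplotype maps
exclude gap columns and lifting a coordinate to MSA space and back is the
identity. Repeat presence is summarized in 300 bp windows *of MSA columns*
(one window grid serves all haplotypes); a window is "gap" for a haplotype
only when every one of its columns is a gap in that row, and any repeat
overlap marks it present (presence wins over partial gaps). Interspersed
repeat fractions use interval unions, so overlapping annotations are not
double-counted. Proper-pair counting considers primary alignments only
(secondary/supplementary excluded) and requires SAM flag 0x2 plus a
mapped target in the requested contig set; reference-to-reference deltas
are reported as (b − a)/a.

## Synthetic fixtures

The generator emulates the study conditions at desk scale from a single
integer seed (one deterministic stream; same seed, byte-identical output):

- default 200 kb haplotype with 8 HLA-like loci plus the DR-plan paralog,
  planted on alternating strands, each with a 4-allele database (allele k
  carries k intronic SNPs; one truncated allele is incomplete in the MSA);
- two C4 cassettes between the class I and class II blocks, built from a
  scaled-down HERV-carrying reference (26 exons, 6 kb HERV intron,
  ~10.8 kb cassette; the real insertion is ~19 kb — the scaling preserves
  every decision rule because the 5 kb deletion floor sits between them);
- planted SNPs/INDELs/SVs at the real MHC's densities (≈2.7 SNPs/kbp,
  ≈0.45 INDELs/kbp, 2 SVs per fixture), confined to inter-feature spacers
  with a 60 bp separation so gene, C4 and typing truth hold on the edited
  assembly; truth coordinates are lifted through the construction CIGAR;
- pileups with capped sequencing noise (errors can never reach a
  majority) and planted discordances at stated allele fractions;
- repeat intervals drawn at random with the realized union fraction
  recorded as truth.

A reduced preset (60 kb, 3 loci, same per-kbp densities) exists for
many-seed sweeps; the 100-seed recovery checks use it so the whole
verification runs in about a minute.

What the fixtures do **not** model: segmental duplications and paralogy
beyond the planted C4 tandem, repeat-mediated microhomology at indel
breakpoints, alignment ambiguity in low-complexity sequence, base-quality
structure in pileups, and real IPD-IMGT/HLA allele relationships. Passing
tests therefore demonstrate correctness of the decision rules and
bookkeeping on unambiguous substrates, not robustness to every real-data
pathology; on real data the alignment inputs (PAF/SAM/VCF) come from the
standard external tools.

## Degenerate inputs and numeric conventions

Empty alignment record lists yield empty projections; a C4-null haplotype
yields an empty genotype string; annotation absence is a valid outcome,
not an error. Thresholds are compared exactly as stated (≥ for the SV
floor and contig quality, strict > for majorities and uncovered
stretches), and the boundary probes in the acceptance suite pin each one
on both sides. Alignment scores are small integers held in int32; the DP
sentinel is −2³⁰.
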