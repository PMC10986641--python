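# mhcforge

A toolkit for characterizing fully resolved assemblies of the human MHC
(Major Histocompatibility Complex), the ~5 Mbp region of chromosome 6 that
contains the HLA genes and is the most polymorphic stretch of the human
genome. It is aimed at groups producing or evaluating complete MHC
haplotype sequences (e.g. from MHC-homozygous cell lines) who need the
bespoke downstream steps that no general-purpose pipeline provides:

- **HLA typing from assembly** — every genomic allele of an
  IPD-IMGT/HLA-style database is placed on the assembly (both strands,
  free end gaps on the assembly side) and the allele minimizing the
  unit-cost edit distance of its best placement is reported; incomplete
  database alleles can be *completed* from the assembled haplotype.
- **C4 genotyping** — copy number, C4A/C4B isotype from the exon-26
  peptide motifs `PCPVLD` / `LSPVIH`, and HERV status (long/L vs short/S)
  from a large deletion between exons 9 and 10 relative to a HERV-carrying
  C4A reference. Genotypes are formatted as haplotype-ordered strings such
  as `AL,BS`.
- **Polymorphism quantification** — pairwise alignments of an assembly
  against a reference are projected onto the reference *longest first*,
  each query base used at most once; SNPs and INDEL events are counted
  from the projection, and insertions/deletions ≥ 1000 bp or unaligned
  stretches > 1000 bp are structural variants. Densities are reported in
  1 kbp non-overlapping windows.
- **Projection-based gene annotation** — reference gene sequences are
  placed (complete-cover alignments only), intron–exon boundaries are
  projected through the CIGAR, and transcripts failing translational
  consistency (start codon, stop codon, no internal stop) are suppressed.
- **Polishing decision rules** — homozygous-VCF substitution; substitution
  of contig alignments with *query cover × identity ≥ 0.99*; and
  dual-technology majority polishing (both pileups agree, each modal
  allele a strict > 50 % majority, no INDEL, differs from the assembly).
- **Structure comparison** — repeat presence in 300 bp windows on a common
  MSA coordinate system, interspersed-repeat fractions, MHC class II
  region extraction (HLA-DRA to 20 kb downstream of HLA-DRB1), DR-group
  classification (DR1/DR2/DR3/DR4/DR8 from the DRB1 allele family and
  DRB3/4/5 carrier status), and proper-pair read-mapping metrics.
- **Synthetic fixtures** — a deterministic generator that plants genes,
  allele databases, C4 cassettes, variants, repeats and pileups with
  machine-readable truth tables, so the whole pipeline is testable with no
  downloads.

## Worked example

Simulate a 120 kb haplotype carrying an `AL,BL` C4 configuration and a DR3
class II structure, then re-derive its properties:

```sh
mhcforge simulate --seed 5 --length 120000 --out fx
mhcforge variants --assembly fx/assembly.fasta --reference fx/reference.fasta \
    --paf fx/alignment.paf --out out_variants
# SNPs=540 INDELs=90 SVs=2
mhcforge c4 --assembly fx/assembly.fasta --c4-ref fx/c4_ref.fasta \
    --exons fx/c4_exons.tsv --out out_c4
# AL,BL
mhcforge type-hla --assembly fx/assembly.fasta --alleles fx/alleles.fasta \
    --msa-dir fx/msa --out out_typing
# typed 9 loci
```

`out_variants/totals.tsv` holds the SNP/INDEL/SV totals of the assembly
relative to the reference (here they equal the planted truth in
`fx/truth.json`); `out_c4/genotype.txt` holds the C4 genotype string, one
`[AB][LS]` label per gene copy in haplotype order; `out_typing/typing.tsv`
lists, per HLA locus (9 here: 8 planted class I/II loci plus the DR-plan
paralog DRB3), the closest database allele and its edit distance (0 = the
assembly carries that allele exactly), and `out_typing/dr_group.txt` the
inferred class II structural group (`DR3`). Every run writes a
`manifest.json` with input checksums and the configuration used.

The same operations are available as a library
(`mhcforge.hla.type_assembly`, `mhcforge.c4.genotype_assembly`,
`mhcforge.variants.count_variants`, ...); see `docs/methods.md` for the
underlying models and conventions.

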