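"""Readers and writers for the standard formats the toolkit touches.

Internally every coordinate is 0-based half-open; 1-based formats (GFF3,
RepeatMasker .out, VCF) are converted at the boundary.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass

import pysam

from .align import AlignmentRecord, parse_cigar

logger = logging.getLogger(__name__)

UNKNOWN_CHARS = frozenset("*.")


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlleleRecord:
    """One named genomic allele, with completeness relative to its locus MSA."""

    allele_name: str
    locus: str
    sequence: str
    is_complete: bool = False
    msa_span: tuple[int, int] | None = None


@dataclass
class VariantCall:
    seq_id: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    zygosity: str  # "hom" | "het"
    kind: str  # "snp" | "ins" | "del"


@dataclass
class RepeatFeature:
    seq_id: str
    start: int
    end: int
    repeat_name: str
    repeat_class_family: str
    strand: str


@dataclass
class ReadAlignment:
    read_id: str
    flags: int
    target_id: str | None
    pos: int
    mapq: int

    PROPER_PAIR = 0x2
    UNMAPPED = 0x4
    SECONDARY = 0x100
    SUPPLEMENTARY = 0x800

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flags & self.PROPER_PAIR) and not bool(
            self.flags & self.UNMAPPED
        )


def _as_text_stream(source) -> io.TextIOBase:
    if isinstance(source, (str, os.PathLike)):
        return open(source)
    return source


def parse_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA into SequenceRecords (residues uppercased, order kept).

    The header is split at the first whitespace into id and description.
    Duplicate ids are an error.
    """
    stream = _as_text_stream(source)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        rid = parts[0]
        if not rid:
            raise ValueError("empty FASTA id")
        if rid in seen:
            raise ValueError(f"duplicate FASTA id: {rid!r}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                id=rid,
                description=parts[1] if len(parts) > 1 else "",
                residues="".join(chunks).upper(),
            )
        )

    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise ValueError("FASTA sequence data before first header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: list[SequenceRecord], stream, width: int = 60) -> None:
    out = _as_text_stream(stream) if not hasattr(stream, "write") else stream
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        out.write(header + "\n")
        for i in range(0, len(rec.residues), width):
            out.write(rec.residues[i : i + width] + "\n")


def allele_locus(allele_name: str) -> str:
    """Locus prefix of an allele name like ``DPA1*02:01:01:01`` -> ``DPA1``."""
    return allele_name.split("*", 1)[0]


def allele_name_key(allele_name: str):
    """Natural-order sort key over colon-separated allele name fields."""
    locus, _, rest = allele_name.partition("*")
    fields = []
    for f in rest.split(":") if rest else []:
        digits = "".join(c for c in f if c.isdigit())
        fields.append((int(digits) if digits else 0, f))
    return (locus, fields)


def parse_allele_db(fasta_source, msa_sources: dict | None = None) -> list[AlleleRecord]:
    """Parse a genomic allele database plus per-locus MSAs.

    ``msa_sources`` maps locus name to an aligned-FASTA stream/path whose
    rows use ``-`` for alignment gaps and ``*``/``.`` for unknown sequence.
    An allele is complete iff its MSA row contains no unknown characters
    (an unknown column anywhere means part of the locus is undefined).
    Alleles absent from the MSA are kept but treated as incomplete.
    """
    alleles = []
    msa_rows: dict[str, str] = {}
    msa_sources = msa_sources or {}
    for locus, source in msa_sources.items():
        for row in parse_fasta(source):
            msa_rows[row.id] = row.residues
    for rec in parse_fasta(fasta_source):
        name = rec.id
        locus = allele_locus(name)
        row = msa_rows.get(name)
        if row is None:
            logger.warning("allele %s absent from locus MSA; treated as incomplete", name)
            alleles.append(AlleleRecord(name, locus, rec.residues, False, None))
            continue
        unknown = [i for i, c in enumerate(row) if c in UNKNOWN_CHARS]
        known = [i for i, c in enumerate(row) if c not in UNKNOWN_CHARS]
        if not known:
            span = None
            complete = False
        else:
            span = (known[0], known[-1] + 1)
            complete = not unknown
        alleles.append(AlleleRecord(name, locus, rec.residues, complete, span))
    return alleles


def parse_paf(source, with_cigar: bool = False) -> list[AlignmentRecord]:
    """Parse PAF lines into AlignmentRecords (coordinates stay 0-based).

    When ``with_cigar`` is set, a ``cg:Z:`` tag with extended CIGAR is
    required on every line.
    """
    stream = _as_text_stream(source)
    records = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(fields)}")
        try:
            rec = AlignmentRecord(
                query_id=fields[0],
                q_len=int(fields[1]),
                q_start=int(fields[2]),
                q_end=int(fields[3]),
                strand=fields[4],
                target_id=fields[5],
                t_len=int(fields[6]),
                t_start=int(fields[7]),
                t_end=int(fields[8]),
                n_matches=int(fields[9]),
                block_length=int(fields[10]),
            )
        except ValueError as exc:
            raise ValueError(f"PAF line {lineno}: {exc}") from exc
        cigar = None
        for tag in fields[12:]:
            if tag.startswith("cg:Z:"):
                cigar = parse_cigar(tag[5:])
        if with_cigar:
            if cigar is None:
                raise ValueError(f"PAF line {lineno}: cg:Z: tag required but missing")
            rec.cigar = cigar
            rec.__post_init__()  # re-validate spans against the CIGAR
        records.append(rec)
    return records


def write_paf(records: list[AlignmentRecord], stream) -> None:
    from .align import cigar_to_str

    for r in records:
        fields = [
            r.query_id,
            str(r.q_len if r.q_len is not None else r.q_end),
            str(r.q_start),
            str(r.q_end),
            r.strand,
            r.target_id,
            str(r.t_len if r.t_len is not None else r.t_end),
            str(r.t_start),
            str(r.t_end),
            str(r.n_matches),
            str(r.block_length),
            "60",
        ]
        if r.cigar is not None:
            fields.append("cg:Z:" + cigar_to_str(r.cigar))
        stream.write("\t".join(fields) + "\n")


def parse_repeatmasker_out(source) -> list[RepeatFeature]:
    """Parse RepeatMasker .out (3 header lines; 1-based inclusive begin/end).

    The ``C`` strand marker is mapped to ``-``; the repeat class/family
    string is preserved verbatim.
    """
    stream = _as_text_stream(source)
    features = []
    for lineno, line in enumerate(stream, 1):
        if lineno <= 3:
            continue
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(f"RepeatMasker line {lineno}: truncated ({len(fields)} fields)")
        begin, end = int(fields[5]), int(fields[6])
        strand = "-" if fields[8] == "C" else fields[8]
        features.append(
            RepeatFeature(
                seq_id=fields[4],
                start=begin - 1,
                end=end,
                strand=strand,
                repeat_name=fields[9],
                repeat_class_family=fields[10],
            )
        )
    return features


def write_repeatmasker_out(features: list[RepeatFeature], stream) -> None:
    """Emit features in RepeatMasker .out layout (1-based inclusive)."""
    stream.write(
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat         position in repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat"
        "         class/family  begin end (left)  ID\n\n"
    )
    for i, f in enumerate(features, 1):
        strand = "C" if f.strand == "-" else "+"
        stream.write(
            f"  500   10.0  0.0  0.0  {f.seq_id}  {f.start + 1} {f.end} (0) "
            f"{strand}  {f.repeat_name}  {f.repeat_class_family}  1 "
            f"{f.end - f.start} (0)  {i}\n"
        )


@dataclass
class GffGene:
    """Flat view of one gene tree parsed back from GFF3 (0-based half-open)."""

    gene_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]


def write_gff3(annotations, stream, source: str = "mhcforge") -> None:
    """Emit gene/mRNA/exon/CDS trees in GFF3 (converting to 1-based inclusive).

    ``annotations`` are duck-typed: gene_name, seq_id, start, end, strand,
    exons (ascending 0-based half-open intervals) and a boolean ``coding``.
    """
    stream.write("##gff-version 3\n")
    for ann in annotations:
        for es, ee in ann.exons:
            if es < ann.start or ee > ann.end:
                raise ValueError(
                    f"exon [{es},{ee}) outside gene bounds of {ann.gene_name}"
                )
        gid = f"gene-{ann.gene_name}"
        mid = f"mrna-{ann.gene_name}"
        base = [ann.seq_id, source]
        strand = ann.strand

        def line(ftype, s, e, attrs):
            stream.write(
                "\t".join(
                    base + [ftype, str(s + 1), str(e), ".", strand, ".", attrs]
                )
                + "\n"
            )

        line("gene", ann.start, ann.end, f"ID={gid};Name={ann.gene_name}")
        line("mRNA", ann.start, ann.end, f"ID={mid};Parent={gid}")
        for i, (es, ee) in enumerate(ann.exons, 1):
            line("exon", es, ee, f"ID=exon-{ann.gene_name}-{i};Parent={mid}")
        if getattr(ann, "coding", True):
            for i, (es, ee) in enumerate(ann.exons, 1):
                line("CDS", es, ee, f"ID=cds-{ann.gene_name}-{i};Parent={mid}")


def parse_gff3(source) -> list[GffGene]:
    stream = _as_text_stream(source)
    genes: dict[str, GffGene] = {}
    mrna_to_gene: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"bad GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attr_str = fields
        attrs = dict(a.split("=", 1) for a in attr_str.split(";") if "=" in a)
        if ftype == "gene":
            name = attrs.get("Name", attrs["ID"])
            genes[attrs["ID"]] = GffGene(
                gene_name=name,
                seq_id=seqid,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                exons=[],
            )
        elif ftype == "mRNA":
            mrna_to_gene[attrs["ID"]] = attrs["Parent"]
        elif ftype == "exon":
            gene = genes[mrna_to_gene[attrs["Parent"]]]
            gene.exons.append((int(start) - 1, int(end)))
    for gene in genes.values():
        gene.exons.sort()
    return list(genes.values())


def read_variant_calls(path: str) -> list[VariantCall]:
    """Read a VCF 4.x into VariantCalls; zygosity comes from the GT field.

    A call is homozygous when every GT allele index is the same non-reference
    allele. Records without samples are treated as homozygous for ALT.
    """
    calls = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            zyg = "hom"
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and None not in gt:
                    non_ref = {g for g in gt}
                    zyg = "hom" if len(non_ref) == 1 and 0 not in non_ref else "het"
            ref = rec.ref
            if len(ref) == 1 and len(alt) == 1:
                kind = "snp"
            elif len(alt) > len(ref):
                kind = "ins"
            else:
                kind = "del"
            calls.append(
                VariantCall(
                    seq_id=rec.chrom,
                    pos=rec.start,
                    ref_allele=ref,
                    alt_allele=alt,
                    zygosity=zyg,
                    kind=kind,
                )
            )
    return calls


def read_sam_alignments(path: str) -> list[ReadAlignment]:
    """Read SAM at header+flag level (no per-base access)."""
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    flags=rec.flag,
                    target_id=rec.reference_name,
                    pos=rec.reference_start if rec.reference_start is not None else -1,
                    mapq=rec.mapping_quality,
                )
            )
    return out
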