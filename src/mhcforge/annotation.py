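"""Projection-based gene annotation.

A gene's reference genomic sequence (from a tiered set of sources) is
aligned to the assembly; only alignments covering the reference sequence in
its entirety produce an annotation, and the highest-scoring one determines
the gene's placement. Intron-exon boundaries are then projected through the
alignment CIGAR, and the deduced transcript is checked for translational
consistency (start codon, stop codon, no nonsense variants). Failing
transcripts are suppressed unless the gene is on a caller-supplied exception
list of genes known to encode incomplete products.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .align import (
    DEFAULT_SCORING,
    AlignmentRecord,
    Scoring,
    parse_cigar,
    revcomp,
)
from .seq_io import SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

TIER_ORDER = ("allele-db", "curated-genomic", "fallback")


@dataclass
class GeneModel:
    gene_name: str
    tier: str
    genomic_sequence: str
    exons: list[tuple[int, int]]  # ascending, on the genomic sequence
    cds_strand: str = "+"
    coding: bool = True

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s <= prev_end or e <= s:
                raise ValueError(f"{self.gene_name}: exons must be ascending, non-overlapping")
            prev_end = e


@dataclass
class GeneAnnotation:
    gene_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    verdict: str | None  # None for pseudogenes (no translation check)
    provenance: str = ""
    coding: bool = True


def select_reference(gene_name: str, tiers: dict[str, dict[str, GeneModel]]) -> GeneModel:
    """Pick the reference model by tier precedence.

    Precedence: allele database > curated genomic set > fallback set
    (mirroring IPD-IMGT/HLA over RefSeqGene over RefSeq).
    """
    for tier in TIER_ORDER:
        model = tiers.get(tier, {}).get(gene_name)
        if model is not None:
            return model
    raise KeyError(f"gene {gene_name} not present in any reference tier")


def _cigar_score(cigar: list[tuple[int, str]], scoring: Scoring = DEFAULT_SCORING) -> float:
    score = 0
    for length, op in cigar:
        if op == "=":
            score += scoring.match * length
        elif op == "X":
            score += scoring.mismatch * length
        else:
            score += scoring.gap_open + scoring.gap_extend * length
    return float(score)


def _trim_terminal_indels(
    cigar: list[tuple[int, str]]
) -> tuple[list[tuple[int, str]], int, int, int, int]:
    """Strip leading/trailing I/D runs; return (cigar, dq0, dt0, dq1, dt1)."""
    dq0 = dt0 = dq1 = dt1 = 0
    while cigar and cigar[0][1] in "ID":
        n, op = cigar.pop(0)
        if op == "I":
            dq0 += n
        else:
            dt0 += n
    while cigar and cigar[-1][1] in "ID":
        n, op = cigar.pop()
        if op == "I":
            dq1 += n
        else:
            dt1 += n
    return cigar, dq0, dt0, dq1, dt1


def edlib_alignment_provider(min_identity: float = 0.9):
    """Alignment provider backed by edlib semi-global placement.

    Returns a callable ``(query_seq, assembly) -> list[AlignmentRecord]``
    searching both strands. Terminal indel runs are trimmed (as any local
    aligner would clip them) and alignments below ``min_identity`` are
    dropped, so heavily disrupted gene copies yield no complete placement.
    """

    def provider(query_seq: str, assembly: SequenceRecord) -> list[AlignmentRecord]:
        qlen = len(query_seq)
        records = []
        for strand, qseq in (("+", query_seq), ("-", revcomp(query_seq))):
            res = edlib.align(qseq, assembly.residues, mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("locations"):
                continue
            t_start, t_end_incl = res["locations"][0]
            cigar = parse_cigar(res["cigar"])
            cigar, dq0, dt0, dq1, dt1 = _trim_terminal_indels(cigar)
            if not cigar:
                continue
            qp_start, qp_end = dq0, qlen - dq1  # in aligned-strand coords
            if strand == "+":
                q_start, q_end = qp_start, qp_end
            else:
                q_start, q_end = qlen - qp_end, qlen - qp_start
            n_matches = sum(n for n, op in cigar if op == "=")
            block = sum(n for n, op in cigar)
            rec = AlignmentRecord(
                query_id="query",
                target_id=assembly.id,
                q_start=q_start,
                q_end=q_end,
                t_start=t_start + dt0,
                t_end=t_end_incl + 1 - dt1,
                strand=strand,
                cigar=cigar,
                n_matches=n_matches,
                block_length=block,
                score=_cigar_score(cigar),
                q_len=qlen,
                t_len=len(assembly.residues),
            )
            if rec.identity >= min_identity:
                records.append(rec)
        return records

    return provider


def place_gene(
    model: GeneModel,
    assembly: SequenceRecord,
    alignments: list[AlignmentRecord],
) -> AlignmentRecord | None:
    """Select the highest-scoring alignment that covers the model entirely.

    Returns None when no complete alignment exists (no annotation is then
    generated). Ties are broken by identity, then by lower assembly
    coordinate.
    """
    qlen = len(model.genomic_sequence)
    complete = [
        r for r in alignments if r.q_start == 0 and r.q_end == qlen
    ]
    if not complete:
        return None
    return min(complete, key=lambda r: (-r.score, -r.identity, r.t_start))


def _query_to_target_map(placement: AlignmentRecord) -> np.ndarray:
    """Per consumed-query-base target coordinate, snapping left inside insertions."""
    qspan = placement.q_end - placement.q_start
    qmap = np.empty(qspan, dtype=np.int64)
    q = 0
    t = placement.t_start
    for length, op in placement.cigar:
        if op in "=X":
            qmap[q : q + length] = np.arange(t, t + length)
            q += length
            t += length
        elif op == "I":
            qmap[q : q + length] = max(t - 1, placement.t_start)
            q += length
        elif op == "D":
            t += length
    return qmap


def project_exons(
    model: GeneModel, placement: AlignmentRecord
) -> list[tuple[int, int]]:
    """Project the model's exon boundaries onto the assembly through the CIGAR.

    Boundaries that fall inside an assembly-relative insertion snap to the
    leftmost valid assembly coordinate. The returned intervals are ascending
    in assembly coordinates regardless of placement strand.
    """
    qlen = len(model.genomic_sequence)
    if placement.q_start != 0 or placement.q_end != qlen:
        raise ValueError("project_exons requires a complete-cover placement")
    qmap = _query_to_target_map(placement)
    out = []
    for s, e in model.exons:
        if placement.strand == "-":
            s, e = qlen - e, qlen - s  # walk coordinates on the aligned strand
        ts = int(qmap[s])
        te = int(qmap[e - 1]) + 1
        out.append((ts, te))
    out.sort()
    return out


def check_translation(
    exons: list[tuple[int, int]], strand: str, assembly: SequenceRecord
) -> str:
    """Translational-consistency verdict for a projected transcript.

    consistent: starts with ATG, ends with a stop codon, and has no in-frame
    internal stop. Otherwise one of start-missing / premature-stop /
    stop-missing / rejected (frame broken: CDS length not a multiple of 3).
    """
    cds = "".join(assembly.residues[s:e] for s, e in exons)
    if strand == "-":
        cds = revcomp(cds)
    if len(cds) < 6 or len(cds) % 3 != 0:
        return "rejected"
    if not cds.startswith("ATG"):
        return "start-missing"
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for codon in codons[:-1]:
        if codon in STOP_CODONS:
            return "premature-stop"
    if codons[-1] not in STOP_CODONS:
        return "stop-missing"
    return "consistent"


def annotate_assembly(
    assembly: SequenceRecord,
    models: list[GeneModel],
    alignment_provider=None,
    exception_genes: frozenset[str] | set[str] = frozenset(),
) -> list[GeneAnnotation]:
    """Annotate all placeable genes, suppressing inconsistent transcripts.

    Pseudogene models (coding=False) skip the translation check. Genes on
    ``exception_genes`` are annotated even with a failing verdict (the
    verdict is recorded). Output is ordered by assembly coordinate.
    """
    provider = alignment_provider or edlib_alignment_provider()
    annotations = []
    for model in models:
        placement = place_gene(model, assembly, provider(model.genomic_sequence, assembly))
        if placement is None:
            continue
        exons = project_exons(model, placement)
        strand = placement.strand if model.cds_strand == "+" else (
            "+" if placement.strand == "-" else "-"
        )
        if model.coding:
            verdict = check_translation(exons, strand, assembly)
            if verdict != "consistent" and model.gene_name not in exception_genes:
                continue
        else:
            verdict = None
        annotations.append(
            GeneAnnotation(
                gene_name=model.gene_name,
                seq_id=assembly.id,
                start=placement.t_start,
                end=placement.t_end,
                strand=strand,
                exons=exons,
                verdict=verdict,
                provenance=f"{model.tier}:{model.gene_name}",
                coding=model.coding,
            )
        )
    annotations.sort(key=lambda a: (a.start, a.gene_name))
    return annotations
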