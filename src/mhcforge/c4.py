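"""Complement C4 genotyping from an assembled MHC haplotype.

C4 varies along three axes of functional importance: tandem copy number (up
to four copies per haplotype), the C4A/C4B isotype, and presence (long, L)
or absence (short, S) of an endogenous retroviral (HERV) insertion in
intron 9 that reduces expression. Copies are located by mapping a
HERV-carrying C4A reference sequence against the assembly; each match is
classified by (i) whether the alignment shows a large deletion relative to
the reference between exons 9 and 10 (HERV status) and (ii) whether the
translated exon-26 peptide contains the isotype-defining motif PCPVLD (C4A)
or LSPVIH (C4B).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import edlib
from Bio.Seq import Seq

from .align import AlignmentRecord, parse_cigar, revcomp
from .seq_io import SequenceRecord

C4A_MOTIF = "PCPVLD"
C4B_MOTIF = "LSPVIH"

# Minimum deletion length (bp, overlapping the HERV interval) that calls a
# short (S) copy; the real insertion is ~19 kb, so a large floor rejects
# ordinary small indels in intron 9.
DEFAULT_DELETION_FLOOR = 5000


@dataclass
class C4Reference:
    """HERV-carrying C4A reference with its exon table.

    ``exons`` maps exon number to a 0-based half-open interval on the
    reference; ``frames`` gives the codon phase at each exon start. The HERV
    interval defaults to the whole of intron 9 (between exons 9 and 10).
    """

    sequence: str
    exons: dict[int, tuple[int, int]]
    frames: dict[int, int]
    herv_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.herv_interval is None:
            self.herv_interval = (self.exons[9][1], self.exons[10][0])

    @classmethod
    def from_files(cls, fasta_path: str, exon_table_path: str) -> "C4Reference":
        from .seq_io import parse_fasta

        seq = parse_fasta(fasta_path)[0].residues
        exons: dict[int, tuple[int, int]] = {}
        frames: dict[int, int] = {}
        with open(exon_table_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                num = int(row["exon_number"])
                exons[num] = (int(row["start"]), int(row["end"]))
                frames[num] = int(row.get("frame", 0))
        return cls(sequence=seq, exons=exons, frames=frames)


@dataclass
class C4CopyCall:
    start: int
    end: int
    isotype: str  # "A" | "B" | "unclassified"
    herv: str  # "L" | "S"
    exon26_peptide: str = ""


@dataclass
class C4Genotype:
    labels: list[str]
    flagged: bool = False

    @property
    def copy_number(self) -> int:
        return len(self.labels)

    @property
    def formatted(self) -> str:
        return ",".join(self.labels)


def _edlib_record(query: str, target: str, target_id: str) -> AlignmentRecord | None:
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    t_start, t_end_incl = res["locations"][0]
    cigar = parse_cigar(res["cigar"])
    n_matches = sum(n for n, op in cigar if op == "=")
    return AlignmentRecord(
        query_id="C4A-ref",
        target_id=target_id,
        q_start=0,
        q_end=len(query),
        t_start=t_start,
        t_end=t_end_incl + 1,
        strand="+",
        cigar=cigar,
        n_matches=n_matches,
        block_length=sum(n for n, op in cigar),
        score=float(-res["editDistance"]),
        q_len=len(query),
        t_len=len(target),
    )


def _segment_placements(
    query: str, target: str, max_hits: int, max_distance: float
) -> list[tuple[int, int]]:
    """All non-overlapping semi-global placements of a segment, best first."""
    hits: list[tuple[int, int]] = []
    masked = target
    for _ in range(max_hits):
        res = edlib.align(query, masked, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_distance:
            break
        s, e = min(res["locations"])
        e += 1
        hits.append((s, e))
        masked = masked[:s] + "\0" * (e - s) + masked[e:]
    return sorted(hits)


def find_c4_copies(
    assembly: SequenceRecord,
    c4ref: C4Reference,
    max_copies: int = 6,
    max_distance_fraction: float = 0.1,
    pairing_slack: int = 500,
) -> list[AlignmentRecord]:
    """Locate placements of the C4 reference on the assembly, in order.

    A unit-cost placement of the whole HERV-carrying reference would score a
    genuine short (S) copy as badly as random sequence, so copies are found
    the way a chaining aligner would: the two HERV-flanking reference
    segments are placed independently on both strands (each within
    ``max_distance_fraction`` of its length), adjacent segment pairs in the
    correct orientation and spacing are chained into copies, and the full
    reference is then globally aligned against each chained span to obtain
    the placement CIGAR. An empty list is a valid outcome (C4-null
    haplotype).
    """
    herv_lo, herv_hi = c4ref.herv_interval
    herv_len = herv_hi - herv_lo
    seq = c4ref.sequence
    seg5, seg3 = seq[:herv_lo], seq[herv_hi:]
    target = assembly.residues
    spans: list[tuple[int, int, str]] = []
    for strand in "+-":
        q5 = seg5 if strand == "+" else revcomp(seg5)
        q3 = seg3 if strand == "+" else revcomp(seg3)
        h5 = _segment_placements(q5, target, max_copies, max_distance_fraction * len(seg5))
        h3 = _segment_placements(q3, target, max_copies, max_distance_fraction * len(seg3))
        # on '+' the 5' segment precedes the 3' segment; on '-' the reverse
        first, second = (h5, h3) if strand == "+" else (h3, h5)
        used: set[tuple[int, int]] = set()
        for fs, fe in first:
            mates = [
                (ss, se)
                for ss, se in second
                if (ss, se) not in used
                and -pairing_slack <= ss - fe <= herv_len + pairing_slack
            ]
            if not mates:
                continue
            ss, se = min(mates)
            used.add((ss, se))
            spans.append((fs, fe, ss, se, strand))
    placements = []
    herv_seq = seq[herv_lo:herv_hi]
    for fs, fe, ss, se, strand in sorted(spans):
        # per-part exact alignments keep a HERV-sized deletion contiguous in
        # the CIGAR (a whole-span unit-cost alignment may scatter it at ties)
        if strand == "+":
            qparts = (seg5, herv_seq, seg3)
        else:
            qparts = (revcomp(seg3), revcomp(herv_seq), revcomp(seg5))
        t1_end = min(fe, ss)
        tparts = (target[fs:t1_end], target[t1_end:ss], target[ss:se])
        cigar: list[tuple[int, str]] = []
        distance = 0
        for qp, tp in zip(qparts, tparts):
            for n, op in _nw_cigar(qp, tp):
                distance += n if op != "=" else 0
                if cigar and cigar[-1][1] == op:
                    cigar[-1] = (cigar[-1][0] + n, op)
                else:
                    cigar.append((n, op))
        n_matches = sum(n for n, op in cigar if op == "=")
        placements.append(
            AlignmentRecord(
                query_id="C4A-ref",
                target_id=assembly.id,
                q_start=0,
                q_end=len(seq),
                t_start=fs,
                t_end=se,
                strand=strand,
                cigar=cigar,
                n_matches=n_matches,
                block_length=sum(n for n, op in cigar),
                score=float(-distance),
                q_len=len(seq),
                t_len=len(target),
            )
        )
    return placements


def _nw_cigar(query: str, target: str) -> list[tuple[int, str]]:
    """Global-alignment CIGAR of two strings, either possibly empty."""
    if not query and not target:
        return []
    if not query:
        return [(len(target), "D")]
    if not target:
        return [(len(query), "I")]
    res = edlib.align(query, target, mode="NW", task="path")
    return parse_cigar(res["cigar"])


def _map_query_interval(
    placement: AlignmentRecord, q_lo: int, q_hi: int
) -> tuple[int, int] | None:
    """Map a query interval to target coordinates through the CIGAR."""
    q = 0
    t = placement.t_start
    t_lo = t_hi = None
    for length, op in placement.cigar:
        if op in "=X":
            if t_lo is None and q_lo < q + length and q_lo >= q:
                t_lo = t + (q_lo - q)
            if q < q_hi <= q + length:
                t_hi = t + (q_hi - q)
            q += length
            t += length
        elif op == "I":
            if t_lo is None and q <= q_lo < q + length:
                t_lo = t
            if q < q_hi <= q + length:
                t_hi = t
            q += length
        elif op == "D":
            t += length
    if t_lo is None or t_hi is None or t_hi <= t_lo:
        return None
    return t_lo, t_hi


def classify_copy(
    placement: AlignmentRecord,
    assembly: SequenceRecord,
    c4ref: C4Reference,
    deletion_floor: int = DEFAULT_DELETION_FLOOR,
) -> C4CopyCall:
    """Classify one C4 copy for HERV status and A/B isotype.

    HERV status is S iff the alignment contains a deletion relative to the
    reference of at least ``deletion_floor`` bp overlapping the HERV
    interval, else L. The isotype is read from the translated exon-26
    peptide; copies whose exon 26 cannot be projected or whose peptide
    carries neither motif are reported as unclassified (HERV status is still
    reported).
    """
    herv_lo, herv_hi = c4ref.herv_interval
    qlen = len(c4ref.sequence)
    # walk query-side deletions (I ops consume reference/query bases that are
    # absent from the assembly)
    herv = "L"
    q = 0
    for length, op in placement.cigar:
        if op in "=XI":
            if op == "I" and length >= deletion_floor:
                lo, hi = (q, q + length) if placement.strand == "+" else (
                    qlen - q - length,
                    qlen - q,
                )
                if lo < herv_hi and hi > herv_lo:
                    herv = "S"
            q += length
    e26_lo, e26_hi = c4ref.exons[26]
    if placement.strand == "-":
        e26_lo, e26_hi = qlen - e26_hi, qlen - e26_lo
    mapped = _map_query_interval(placement, e26_lo, e26_hi)
    if mapped is None:
        return C4CopyCall(placement.t_start, placement.t_end, "unclassified", herv)
    t_lo, t_hi = mapped
    seq = assembly.residues[t_lo:t_hi]
    if placement.strand == "-":
        seq = revcomp(seq)
    frame = c4ref.frames.get(26, 0)
    coding = seq[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return C4CopyCall(placement.t_start, placement.t_end, "unclassified", herv)
    peptide = str(Seq(coding).translate())
    has_a = C4A_MOTIF in peptide
    has_b = C4B_MOTIF in peptide
    if has_a == has_b:  # neither, or (pathological) both
        isotype = "unclassified"
    else:
        isotype = "A" if has_a else "B"
    return C4CopyCall(placement.t_start, placement.t_end, isotype, herv, peptide)


def genotype_string(calls: list[C4CopyCall]) -> C4Genotype:
    """Format per-copy calls into the haplotype-order genotype string.

    Each copy contributes an isotype letter plus a HERV letter (e.g. "AL");
    unclassified isotypes appear as "?" and flag the genotype.
    """
    labels = []
    flagged = False
    for call in calls:
        iso = call.isotype if call.isotype in ("A", "B") else "?"
        flagged = flagged or iso == "?"
        labels.append(iso + call.herv)
    return C4Genotype(labels=labels, flagged=flagged)


def genotype_assembly(
    assembly: SequenceRecord,
    c4ref: C4Reference,
    deletion_floor: int = DEFAULT_DELETION_FLOOR,
) -> tuple[list[C4CopyCall], C4Genotype]:
    """Convenience wrapper: find, classify and format all C4 copies."""
    placements = find_c4_copies(assembly, c4ref)
    calls = [classify_copy(p, assembly, c4ref, deletion_floor) for p in placements]
    return calls, genotype_string(calls)
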