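"""Assembly polishing decision rules.

Three independent correction operators: (1) substitution of homozygous
variant calls into the assembly; (2) substitution of high-quality contig
alignments, where "high quality" means query cover times alignment identity
of at least 0.99; (3) dual-technology majority polishing, where a base is
replaced only when the long-read and short-read pileups agree on a modal
allele that is a strict majority (> 50%) in both, is a single base (no
INDEL), and differs from the assembly. All three operators are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentRecord, revcomp, quality
from .seq_io import VariantCall

logger = logging.getLogger(__name__)


@dataclass
class PileupColumn:
    pos: int
    counts: dict[str, dict[str, int]]  # technology -> allele -> count

    def depth(self, tech: str) -> int:
        return sum(self.counts.get(tech, {}).values())

    def modal_allele(self, tech: str) -> tuple[str | None, int]:
        alleles = self.counts.get(tech, {})
        if not alleles:
            return None, 0
        # deterministic: highest count, ties by allele string
        allele = min(alleles, key=lambda a: (-alleles[a], a))
        return allele, alleles[allele]


@dataclass(frozen=True)
class MajorityPolicy:
    min_fraction: float = 0.5  # strict: modal count must exceed this fraction
    require_both_technologies: bool = True
    forbid_indel: bool = True


@dataclass(frozen=True)
class SubstitutionPolicy:
    min_quality: float = 0.99


def apply_homozygous_variants(
    assembly: str, calls: list[VariantCall]
) -> tuple[str, int]:
    """Substitute homozygous calls into the assembly sequence.

    Heterozygous calls are skipped. Calls are applied right-to-left so the
    printed coordinates of downstream calls need no lift-over. A REF allele
    that does not match the assembly is an error naming the position.
    """
    seq = assembly
    n_applied = 0
    for call in sorted(calls, key=lambda c: -c.pos):
        if assembly[call.pos : call.pos + len(call.ref_allele)] != call.ref_allele:
            raise ValueError(
                f"REF allele mismatch at position {call.pos}: expected "
                f"{call.ref_allele!r}, assembly has "
                f"{assembly[call.pos:call.pos + len(call.ref_allele)]!r}"
            )
        if call.zygosity != "hom":
            continue
        seq = seq[: call.pos] + call.alt_allele + seq[call.pos + len(call.ref_allele) :]
        n_applied += 1
    return seq, n_applied


def substitute_contigs(
    assembly: str,
    contig_records: list[tuple[AlignmentRecord, str]],
    policy: SubstitutionPolicy = SubstitutionPolicy(),
) -> str:
    """Substitute high-quality contig alignments into the assembly.

    Contigs whose query cover x identity reaches ``policy.min_quality`` are
    substituted over their aligned target intervals, processed in descending
    quality (ties: lower target coordinate); a later substitution
    overlapping an already-substituted interval is skipped and logged. The
    result is independent of input order.
    """
    qualifying = []
    for rec, contig_seq in contig_records:
        q = quality(rec, rec.q_len if rec.q_len is not None else len(contig_seq))
        if q >= policy.min_quality:
            qualifying.append((q, rec, contig_seq))
    qualifying.sort(key=lambda item: (-item[0], item[1].t_start, item[1].query_id))
    chosen: list[tuple[AlignmentRecord, str]] = []
    claimed: list[tuple[int, int]] = []
    for q, rec, contig_seq in qualifying:
        if any(rec.t_start < e and rec.t_end > s for s, e in claimed):
            logger.info(
                "skipping contig %s: overlaps an earlier substitution", rec.query_id
            )
            continue
        claimed.append((rec.t_start, rec.t_end))
        chosen.append((rec, contig_seq))
    seq = assembly
    for rec, contig_seq in sorted(chosen, key=lambda item: -item[0].t_start):
        piece = contig_seq[rec.q_start : rec.q_end]
        if rec.strand == "-":
            piece = revcomp(piece)
        seq = seq[: rec.t_start] + piece + seq[rec.t_end :]
    return seq


def majority_polish(
    assembly: str,
    pileup: list[PileupColumn],
    policy: MajorityPolicy = MajorityPolicy(),
) -> tuple[str, int]:
    """Replace assembly bases by the agreed dual-technology majority allele.

    A position changes iff the modal alleles of both technologies are
    identical, each is a strict majority of its column depth, the allele is
    a single base (no INDEL token), and it disagrees with the assembly.
    Length is always preserved. Depth-0 columns never change.
    """
    seq = list(assembly)
    n_changes = 0
    for col in pileup:
        if col.pos < 0 or col.pos >= len(assembly):
            raise IndexError(f"pileup position {col.pos} outside assembly")
        techs = sorted(col.counts)
        if policy.require_both_technologies and len(techs) < 2:
            continue
        modal_alleles = set()
        ok = True
        for tech in techs:
            allele, count = col.modal_allele(tech)
            depth = col.depth(tech)
            if allele is None or depth == 0 or count <= policy.min_fraction * depth:
                ok = False
                break
            modal_alleles.add(allele)
        if not ok or len(modal_alleles) != 1:
            continue
        allele = modal_alleles.pop()
        if policy.forbid_indel and (len(allele) != 1 or allele not in "ACGT"):
            continue
        if seq[col.pos] != allele:
            seq[col.pos] = allele
            n_changes += 1
    return "".join(seq), n_changes
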