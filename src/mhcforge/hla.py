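"""Closest-allele HLA typing of an assembly against a genomic allele database.

For each locus, every database allele is placed on the assembly (both
strands) with free end gaps on the assembly side, and the allele minimizing
the unit-cost edit distance of its best placement is reported. If that
allele is incompletely defined relative to the locus MSA, the locus sequence
is extracted using the placement of the closest *complete* allele, which
also allows completing the definition of the incomplete allele from the
assembled haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .align import revcomp
from .seq_io import AlleleRecord, SequenceRecord, allele_name_key

logger = logging.getLogger(__name__)

# An allele whose best placement costs more than this fraction of its length
# is treated as absent from the assembly (e.g. DRB3/4/5 on haplotypes that
# do not carry the paralog).
ABSENCE_DISTANCE_FRACTION = 0.2


@dataclass
class Placement:
    start: int
    end: int
    strand: str
    distance: int


@dataclass
class LocusTypingResult:
    locus: str
    best_allele_name: str | None
    edit_distance: int
    best_is_complete: bool
    matches_reference_type: bool | None
    extracted_sequence: str | None
    added_bases: int
    present: bool = True


def _best_placement(allele_seq: str, assembly_seq: str) -> Placement:
    """Best semi-global placement of an allele on either assembly strand."""
    fwd = edlib.align(allele_seq, assembly_seq, mode="HW", task="locations")
    rc = edlib.align(revcomp(allele_seq), assembly_seq, mode="HW", task="locations")
    if fwd["editDistance"] <= rc["editDistance"]:
        res, strand = fwd, "+"
    else:
        res, strand = rc, "-"
    start, end = min(res["locations"])  # lowest-coordinate optimal placement
    return Placement(start=start, end=end + 1, strand=strand, distance=res["editDistance"])


def closest_allele(
    assembly: SequenceRecord, alleles: list[AlleleRecord]
) -> tuple[str, int]:
    """Return (allele_name, edit_distance) of the closest database allele.

    Ties are broken deterministically: complete alleles are preferred over
    incomplete ones, then the lowest allele name in natural field order.
    """
    if not alleles:
        raise ValueError("closest_allele requires at least one allele")
    best = None
    for allele in alleles:
        p = _best_placement(allele.sequence, assembly.residues)
        key = (p.distance, not allele.is_complete, allele_name_key(allele.allele_name))
        if best is None or key < best[0]:
            best = (key, allele, p)
    _, allele, p = best
    if p.distance > ABSENCE_DISTANCE_FRACTION * len(allele.sequence):
        raise LookupError(f"locus absent: no allele of {allele.locus} places on the assembly")
    return allele.allele_name, p.distance


def extract_locus(
    assembly: SequenceRecord, alleles: list[AlleleRecord], best: str
) -> tuple[str, int, int, str]:
    """Extract the full locus sequence from the assembly.

    Returns (sequence, start, end, strand) with the sequence strand-normalized
    to gene orientation. If the best allele is complete, the extraction
    interval is its own best placement; if it is incomplete, the interval is
    taken from the best placement of the closest complete allele at the locus.
    """
    by_name = {a.allele_name: a for a in alleles}
    best_allele = by_name[best]
    if best_allele.is_complete:
        anchor = best_allele
    else:
        complete = [a for a in alleles if a.is_complete]
        if not complete:
            raise LookupError(
                f"no complete allele at locus {best_allele.locus}; cannot extract"
            )
        anchor = min(
            complete,
            key=lambda a: (
                _best_placement(a.sequence, assembly.residues).distance,
                allele_name_key(a.allele_name),
            ),
        )
    p = _best_placement(anchor.sequence, assembly.residues)
    seq = assembly.residues[p.start : p.end]
    if p.strand == "-":
        seq = revcomp(seq)
    return seq, p.start, p.end, p.strand


def complete_allele(
    incomplete: AlleleRecord, extracted_sequence: str
) -> tuple[str, int]:
    """Fill the unknown flanks of an incomplete allele from the extraction.

    The allele's known span must occur in the extracted locus sequence with
    edit distance 0; otherwise completion would be chimeric and an error is
    raised. Returns (completed_sequence, added_bases).
    """
    if incomplete.is_complete:
        return incomplete.sequence, 0
    core = incomplete.sequence
    if core not in extracted_sequence:
        raise ValueError(
            f"known span of {incomplete.allele_name} mismatches the extracted "
            "locus sequence; completion would be chimeric"
        )
    return extracted_sequence, len(extracted_sequence) - len(core)


def type_assembly(
    assembly: SequenceRecord,
    allele_db: list[AlleleRecord],
    loci: list[str],
    reference_types: dict[str, str] | None = None,
) -> list[LocusTypingResult]:
    """Type one assembly at the given loci against the allele database."""
    by_locus: dict[str, list[AlleleRecord]] = {}
    for allele in allele_db:
        by_locus.setdefault(allele.locus, []).append(allele)
    results = []
    for locus in loci:
        alleles = by_locus.get(locus)
        if not alleles:
            raise KeyError(f"locus {locus} not in allele database")
        try:
            name, dist = closest_allele(assembly, alleles)
        except LookupError:
            results.append(
                LocusTypingResult(
                    locus=locus,
                    best_allele_name=None,
                    edit_distance=-1,
                    best_is_complete=False,
                    matches_reference_type=None,
                    extracted_sequence=None,
                    added_bases=0,
                    present=False,
                )
            )
            continue
        best_allele = next(a for a in alleles if a.allele_name == name)
        matches = None
        if reference_types and locus in reference_types:
            matches = name == reference_types[locus]
        extracted = None
        added = 0
        if matches is False or not best_allele.is_complete:
            try:
                extracted, _, _, _ = extract_locus(assembly, alleles, name)
            except LookupError as exc:
                logger.warning("%s", exc)
            if extracted is not None and not best_allele.is_complete and dist == 0:
                try:
                    _, added = complete_allele(best_allele, extracted)
                except ValueError as exc:
                    logger.warning("%s", exc)
        results.append(
            LocusTypingResult(
                locus=locus,
                best_allele_name=name,
                edit_distance=dist,
                best_is_complete=best_allele.is_complete,
                matches_reference_type=matches,
                extracted_sequence=extracted,
                added_bases=added,
            )
        )
    return results
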