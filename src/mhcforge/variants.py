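"""Polymorphism quantification from once-only projections.

SNPs are counted per projected position where the query and reference
alleles differ (N never counts). Insertion/deletion events shorter than the
SV floor are INDELs; events of at least the floor (default 1000 bp), and
never-projected stretches of more than the uncovered floor on either
sequence, are structural variants. The classes are disjoint. Windowed
densities use non-overlapping windows (default 1 kbp) with each event
assigned to the window of its reference start coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ProjectionMap
from .hla import LocusTypingResult

ACGT_BYTES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SvPolicy:
    sv_floor: int = 1000  # indel events of >= this length are SVs
    uncovered_floor: int = 1000  # unprojected stretches of > this length are SVs
    variant_window: int = 1000

    def __post_init__(self) -> None:
        if self.sv_floor <= 0 or self.uncovered_floor <= 0 or self.variant_window <= 0:
            raise ValueError("policy floors must be positive")


@dataclass(frozen=True)
class Class2Policy:
    anchor_start_gene: str = "HLA-DRA"
    anchor_end_gene: str = "HLA-DRB1"
    downstream_pad: int = 20_000


@dataclass
class VariantCounts:
    snps: int
    indels: int
    svs: int
    snp_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    indel_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sv_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def count_variants(projection: ProjectionMap, policy: SvPolicy = SvPolicy()) -> VariantCounts:
    """Count SNPs, INDEL events and SVs from a projection map."""
    filled = projection.slots >= 0
    ref_arr = np.frombuffer(projection.ref_seq.encode(), dtype="S1")
    proj = projection.alleles
    valid = (
        filled
        & (proj != ref_arr)
        & np.isin(ref_arr, ACGT_BYTES)
        & np.isin(proj, ACGT_BYTES)
    )
    snp_positions = np.flatnonzero(valid).astype(np.int64)

    indel_pos: list[int] = []
    sv_pos: list[int] = []
    for ref_pos, seq in projection.insertions:
        (sv_pos if len(seq) >= policy.sv_floor else indel_pos).append(ref_pos)
    for t_start, t_end in projection.deletions:
        (sv_pos if t_end - t_start >= policy.sv_floor else indel_pos).append(t_start)
    for start, end in projection.uncovered_ref_intervals():
        if end - start > policy.uncovered_floor:
            sv_pos.append(start)
    n_query_sv = 0
    for start, end in projection.unprojected_query_intervals():
        if end - start > policy.uncovered_floor:
            n_query_sv += 1
    indel_positions = np.array(sorted(indel_pos), dtype=np.int64)
    sv_positions = np.array(sorted(sv_pos), dtype=np.int64)
    return VariantCounts(
        snps=len(snp_positions),
        indels=len(indel_positions),
        svs=len(sv_positions) + n_query_sv,
        snp_positions=snp_positions,
        indel_positions=indel_positions,
        sv_positions=sv_positions,
    )


def window_density(
    counts: VariantCounts, ref_length: int, window: int = 1000
) -> pd.DataFrame:
    """Per-window variant counts (final partial window included).

    Events are assigned by reference start coordinate; SVs located on the
    query only (never-projected query stretches) have no reference start and
    are not windowed.
    """
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    n_windows = -(-ref_length // window)
    edges = np.arange(n_windows + 1) * window

    def histo(positions: np.ndarray) -> np.ndarray:
        return np.histogram(positions, bins=np.minimum(edges, ref_length))[0]

    return pd.DataFrame(
        {
            "window_start": edges[:-1],
            "window_end": np.minimum(edges[1:], ref_length),
            "snps": histo(counts.snp_positions),
            "indels": histo(counts.indel_positions),
            "svs": histo(counts.sv_positions),
        }
    )


def class2_region(
    annotations, policy: Class2Policy = Class2Policy(), assembly_length: int | None = None
) -> tuple[int, int]:
    """MHC class II interval: from HLA-DRA to 20 kb downstream of HLA-DRB1.

    "Downstream" is taken in increasing haplotype coordinate; the interval is
    clipped to the assembly bounds when a length is given.
    """
    by_name = {a.gene_name: a for a in annotations}
    start_gene = by_name.get(policy.anchor_start_gene)
    end_gene = by_name.get(policy.anchor_end_gene)
    if start_gene is None or end_gene is None:
        missing = policy.anchor_start_gene if start_gene is None else policy.anchor_end_gene
        raise LookupError(f"class II anchor gene {missing} not annotated")
    start = start_gene.start
    end = end_gene.end + policy.downstream_pad
    if assembly_length is not None:
        end = min(end, assembly_length)
    return start, end


# DR-group rules: admissible DRB1 first fields and the exact required set of
# DRB3/4/5 paralogs (mutual exclusivity holds by construction).
DR_GROUP_RULES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "DR1": (frozenset({"01", "10"}), frozenset()),
    "DR2": (frozenset({"15", "16"}), frozenset({"DRB5"})),
    "DR3": (frozenset({"03", "11", "12", "13", "14"}), frozenset({"DRB3"})),
    "DR4": (frozenset({"04", "07", "09"}), frozenset({"DRB4"})),
    "DR8": (frozenset({"08"}), frozenset()),
}


def classify_dr_group(typing: list[LocusTypingResult]) -> str:
    """Classify the MHC class II structure from DRB1 and DRB3/4/5 status.

    DR1: DRB1*01/*10 with no DRB3-5; DR2: DRB1*15/*16 with DRB5;
    DR3: DRB1*03/*11/*12/*13/*14 with DRB3; DR4: DRB1*04/*07/*09 with DRB4;
    DR8: DRB1*08 with no DRB3-5. Anything else is "unclassified".
    """
    by_locus = {t.locus: t for t in typing}
    drb1 = by_locus.get("DRB1")
    if drb1 is None or not drb1.present or drb1.best_allele_name is None:
        return "unclassified"
    first_field = drb1.best_allele_name.partition("*")[2].split(":")[0]
    paralogs = frozenset(
        locus
        for locus in ("DRB3", "DRB4", "DRB5")
        if locus in by_locus and by_locus[locus].present
    )
    for label, (fields, required) in DR_GROUP_RULES.items():
        if first_field in fields and paralogs == required:
            return label
    return "unclassified"
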