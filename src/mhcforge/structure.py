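"""Cross-haplotype structure comparison in common MSA coordinates.

A multiple sequence alignment of the haplotypes provides a shared
coordinate system; repeat annotations are lifted into it and summarized in
non-overlapping windows (default 300 bp of MSA columns). Also provides the
interspersed-repeat fraction of a region and the comparative proper-pair
read-mapping metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import ReadAlignment, RepeatFeature, SequenceRecord

GAP_CHARS = frozenset("-.")

# presence-matrix cell codes
ABSENT, PRESENT, GAP = 0, 1, 2
CELL_LABELS = {ABSENT: "absent", PRESENT: "present", GAP: "gap"}


@dataclass
class MsaCoordinateMap:
    width: int
    pos_to_col: dict[str, np.ndarray]  # per haplotype: sequence pos -> MSA column

    def to_column(self, hap_id: str, pos: int) -> int:
        return int(self.pos_to_col[hap_id][pos])

    def to_position(self, hap_id: str, col: int) -> int | None:
        """Sequence position at an MSA column, or None on a gap column."""
        cols = self.pos_to_col[hap_id]
        idx = np.searchsorted(cols, col)
        if idx < len(cols) and cols[idx] == col:
            return int(idx)
        return None

    def lift_interval(self, hap_id: str, start: int, end: int) -> tuple[int, int]:
        """Lift a half-open sequence interval to half-open MSA columns."""
        cols = self.pos_to_col[hap_id]
        return int(cols[start]), int(cols[end - 1]) + 1


def build_coordinate_map(msa_rows: list[SequenceRecord]) -> MsaCoordinateMap:
    """Build position<->column maps from an aligned FASTA (equal-width rows)."""
    if not msa_rows:
        raise ValueError("empty MSA")
    width = len(msa_rows[0].residues)
    maps = {}
    for row in msa_rows:
        if len(row.residues) != width:
            raise ValueError(f"MSA row {row.id} has width {len(row.residues)} != {width}")
        arr = np.frombuffer(row.residues.encode(), dtype="S1")
        maps[row.id] = np.flatnonzero(~np.isin(arr, [b"-", b"."])).astype(np.int64)
    return MsaCoordinateMap(width=width, pos_to_col=maps)


def presence_matrix(
    repeats_by_hap: dict[str, list[RepeatFeature]],
    coord_map: MsaCoordinateMap,
    window: int = 300,
) -> tuple[list[str], np.ndarray]:
    """Windowed repeat presence per haplotype, on the MSA column grid.

    A window is marked present for a haplotype when any repeat interval
    (lifted to MSA columns) overlaps it; a window is a gap only when every
    one of its columns is a gap in that haplotype's row; otherwise absent.
    Presence wins over gap. Returns (haplotype ids, matrix of cell codes).
    """
    hap_ids = sorted(repeats_by_hap)
    n_windows = -(-coord_map.width // window)
    matrix = np.full((len(hap_ids), n_windows), ABSENT, dtype=np.int8)
    for i, hap in enumerate(hap_ids):
        cols = coord_map.pos_to_col[hap]
        occupied = np.zeros(n_windows, dtype=bool)
        np.logical_or.at(occupied, cols // window, True)
        matrix[i, ~occupied] = GAP
        seq_len = len(cols)
        for feat in repeats_by_hap[hap]:
            if feat.start < 0 or feat.end > seq_len:
                raise ValueError(
                    f"repeat {feat.repeat_name} outside {hap} bounds [0,{seq_len})"
                )
            c_lo, c_hi = coord_map.lift_interval(hap, feat.start, feat.end)
            matrix[i, c_lo // window : (c_hi - 1) // window + 1] = PRESENT
    return hap_ids, matrix


def repeat_fraction(
    repeats: list[RepeatFeature], region: tuple[int, int]
) -> float:
    """Fraction of a region covered by the union of repeat intervals."""
    start, end = region
    if end <= start:
        raise ValueError("empty region")
    clipped = sorted(
        (max(f.start, start), min(f.end, end)) for f in repeats if f.end > start and f.start < end
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / (end - start)


def proper_pair_counts(
    read_alignments: list[ReadAlignment], target_ids: set[str]
) -> tuple[dict[str, int], int]:
    """Count proper-pair primary alignments per target, plus total mapped reads.

    Only primary alignments are considered (secondary and supplementary
    records are excluded). The per-target count requires the proper-pair
    flag; the whole-genome count is all mapped primary alignments.
    """
    per_target = {t: 0 for t in sorted(target_ids)}
    total_mapped = 0
    for rec in read_alignments:
        if rec.flags & (ReadAlignment.SECONDARY | ReadAlignment.SUPPLEMENTARY):
            continue
        if rec.flags & ReadAlignment.UNMAPPED:
            continue
        total_mapped += 1
        if rec.is_proper_pair and rec.target_id in per_target:
            per_target[rec.target_id] += 1
    return per_target, total_mapped


def percent_difference(a: float, b: float) -> float:
    """Relative difference (b - a) / a, as used to compare two references."""
    if a == 0:
        raise ZeroDivisionError("baseline count is zero")
    return (b - a) / a
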