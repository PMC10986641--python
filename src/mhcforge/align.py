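"""Pairwise alignment, alignment quality, and once-only projection.

Coordinates are 0-based half-open throughout. CIGAR operations follow the
extended SAM alphabet: ``=`` (match), ``X`` (mismatch), ``I`` (insertion to
the query, i.e. query bases absent from the target) and ``D`` (deletion from
the query, i.e. target bases absent from the query).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

QUERY_CONSUMING = frozenset("=XI")
TARGET_CONSUMING = frozenset("=XD")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(text: str) -> list[tuple[int, str]]:
    """Parse an extended-CIGAR string into ``(length, op)`` tuples.

    Adjacent operations of the same kind are merged; ``M`` is rejected
    because match/mismatch must be distinguished for identity computation.
    """
    ops: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR near {text[pos:pos + 10]!r}")
        pos = m.end()
        length, op = int(m.group(1)), m.group(2)
        if op == "M":
            raise ValueError("ambiguous 'M' operation; extended CIGAR (=/X) required")
        if length < 1:
            raise ValueError("CIGAR op length must be >= 1")
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + length, op)
        else:
            ops.append((length, op))
    if pos != len(text):
        raise ValueError(f"malformed CIGAR near {text[pos:pos + 10]!r}")
    return ops


def cigar_to_str(ops: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


@dataclass
class AlignmentRecord:
    """One pairwise alignment between a query and a target sequence."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"
    cigar: list[tuple[int, str]] | None = None
    n_matches: int = 0
    block_length: int = 0
    score: float = 0.0
    q_len: int | None = None
    t_len: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.cigar is not None:
            q_span = sum(n for n, op in self.cigar if op in QUERY_CONSUMING)
            t_span = sum(n for n, op in self.cigar if op in TARGET_CONSUMING)
            if q_span != self.q_end - self.q_start:
                raise ValueError(
                    f"CIGAR query span {q_span} != q_end-q_start "
                    f"{self.q_end - self.q_start}"
                )
            if t_span != self.t_end - self.t_start:
                raise ValueError(
                    f"CIGAR target span {t_span} != t_end-t_start "
                    f"{self.t_end - self.t_start}"
                )

    @property
    def identity(self) -> float:
        """Matches over alignment block length, in [0, 1]."""
        if self.block_length == 0:
            return 0.0
        return self.n_matches / self.block_length

    @property
    def target_span(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()

_NEG = np.int32(-(2**30))


def global_align(
    seq_a: str,
    seq_b: str,
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentRecord:
    """Optimal global alignment with affine gap penalties (Gotoh).

    ``seq_a`` is the query (rows), ``seq_b`` the target (columns). A gap of
    length L costs ``gap_open + L * gap_extend``. The DP is exact and stores
    full traceback matrices, so it is intended for desk-scale inputs (up to
    a few tens of kbp); larger alignments should come from an external
    aligner via PAF. Tie-breaking is deterministic: at equal score the
    traceback prefers a match/mismatch over a query insertion over a
    deletion.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_align requires non-empty sequences")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend
    is_n = np.uint8(ord("N"))
    # substitution scores for row i against all of b (N never matches)
    j_idx = np.arange(1, m + 1)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # ends in =/X
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # ends in I (consumes a)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # ends in D (consumes b)
    M[0, 0] = 0
    E[1:, 0] = go + ge * np.arange(1, n + 1)
    F[0, 1:] = go + ge * j_idx

    k_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        sub = np.where(
            (a[i - 1] == b) & (a[i - 1] != is_n) & (b != is_n),
            scoring.match,
            scoring.mismatch,
        )
        M[i, 1:] = prev_best[:-1] + sub
        E[i, 1:] = np.maximum(
            E[i - 1, 1:] + ge, np.maximum(M[i - 1, 1:], F[i - 1, 1:]) + go + ge
        )
        # F has an intra-row dependency, but opening a D gap from an F state
        # is never better than extending it, so a running max over (M, E)
        # openings suffices: F[i,j] = go + ge*j + max_{k<j}(src[k] - ge*k).
        src = np.maximum(M[i], E[i])
        run = np.maximum.accumulate(src - ge * k_idx)
        F[i, 1:] = run[:-1] + ge * j_idx + go

    # traceback
    ops: list[tuple[int, str]] = []

    def push(op: str) -> None:
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + 1, op)
        else:
            ops.append((1, op))

    i, j = n, m
    best = max(M[n, m], E[n, m], F[n, m])
    state = "M" if M[n, m] == best else ("E" if E[n, m] == best else "F")
    n_matches = 0
    while i > 0 or j > 0:
        if i == 0:
            push("D")
            j -= 1
            continue
        if j == 0:
            push("I")
            i -= 1
            continue
        if state == "M":
            matched = (
                a[i - 1] == b[j - 1] and a[i - 1] != is_n and b[j - 1] != is_n
            )
            push("=" if matched else "X")
            if matched:
                n_matches += 1
            prev = max(M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            if M[i - 1, j - 1] == prev:
                state = "M"
            elif E[i - 1, j - 1] == prev:
                state = "E"
            else:
                state = "F"
            i -= 1
            j -= 1
        elif state == "E":
            push("I")
            # prefer continuing the gap at equal score (canonical left-aligned runs)
            if E[i, j] == E[i - 1, j] + ge:
                state = "E"
            elif E[i, j] == M[i - 1, j] + go + ge:
                state = "M"
            else:
                state = "F"
            i -= 1
        else:  # F
            push("D")
            if F[i, j] == F[i, j - 1] + ge:
                state = "F"
            elif F[i, j] == M[i, j - 1] + go + ge:
                state = "M"
            else:
                state = "E"
            j -= 1
    ops.reverse()
    # merge handled by push; compute block length
    block = sum(length for length, _ in ops)
    return AlignmentRecord(
        query_id=query_id,
        target_id=target_id,
        q_start=0,
        q_end=n,
        t_start=0,
        t_end=m,
        strand="+",
        cigar=ops,
        n_matches=n_matches,
        block_length=block,
        score=float(best),
        q_len=n,
        t_len=m,
    )


def quality(record: AlignmentRecord, query_length: int) -> float:
    """Query cover times alignment identity, in [0, 1].

    This is the composite statistic used to accept "high-quality" contig
    alignments during polishing (threshold 0.99 by default there).
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if record.q_end > query_length:
        raise ValueError("q_end exceeds query_length")
    cover = (record.q_end - record.q_start) / query_length
    return cover * record.identity


@dataclass
class ProjectionMap:
    """Once-only projection of a query sequence onto a reference.

    ``slots[t]`` holds the query position projected onto reference position
    ``t`` (-1: never covered; -2: covered by a deletion event). Each query
    base is used at most once, even when overlapping alignment records are
    supplied. Insertion events (query bases between two reference positions)
    and deletion events (reference bases absent from the query) are recorded
    once per CIGAR run.
    """

    ref_id: str
    query_id: str
    ref_seq: str
    query_seq: str
    slots: np.ndarray
    alleles: np.ndarray  # per-reference-position projected query base (b"" if none)
    query_used: np.ndarray
    insertions: list[tuple[int, str]] = field(default_factory=list)  # (ref_pos, seq)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # ref interval

    @property
    def ref_length(self) -> int:
        return len(self.ref_seq)

    @property
    def query_length(self) -> int:
        return len(self.query_seq)

    def _runs(self, mask: np.ndarray) -> list[tuple[int, int]]:
        if not mask.any():
            return []
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return list(zip(starts.tolist(), ends.tolist()))

    def uncovered_ref_intervals(self) -> list[tuple[int, int]]:
        """Reference stretches with no projected alignment (deletions excluded)."""
        return self._runs(self.slots == -1)

    def unprojected_query_intervals(self) -> list[tuple[int, int]]:
        """Query stretches never projected onto the reference."""
        return self._runs(~self.query_used)

    def n_projected(self) -> int:
        return int(self.query_used.sum())


def _sort_key(rec: AlignmentRecord) -> tuple[int, int, int]:
    return (-(rec.t_end - rec.t_start), -rec.n_matches, rec.t_start)


def project(
    records: list[AlignmentRecord], query_seq: str, ref_seq: str
) -> ProjectionMap:
    """Build a ProjectionMap from alignment records, longest target span first.

    Records are processed in descending target-span order (ties: more matches
    first, then lower ``t_start``), so the result does not depend on input
    order. Within a record, an aligned base pair is written only if the query
    base is unused and the reference slot is empty; an insertion is recorded
    only if all of its query bases are unused; a deletion only if all of its
    reference slots are empty. Minus-strand records are walked in reference
    orientation with complemented query bases.
    """
    query_seq = query_seq.upper()
    ref_seq = ref_seq.upper()
    ref_len, q_len = len(ref_seq), len(query_seq)
    for rec in records:
        if rec.cigar is None:
            raise ValueError("projection requires CIGARs on all records")
        if rec.q_end > q_len or rec.t_end > ref_len:
            raise ValueError(
                f"record coordinates exceed sequence lengths "
                f"(q_end={rec.q_end}, t_end={rec.t_end})"
            )
    pm = ProjectionMap(
        ref_id=records[0].target_id if records else "ref",
        query_id=records[0].query_id if records else "query",
        ref_seq=ref_seq,
        query_seq=query_seq,
        slots=np.full(ref_len, -1, dtype=np.int64),
        alleles=np.zeros(ref_len, dtype="S1"),
        query_used=np.zeros(q_len, dtype=bool),
    )
    qarr = np.frombuffer(query_seq.encode(), dtype="S1")
    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"N": b"N"}
    for rec in sorted(records, key=_sort_key):
        minus = rec.strand == "-"
        t = rec.t_start
        # on '-', the CIGAR pairs ascending target with descending query
        q = rec.q_end - 1 if minus else rec.q_start
        step = -1 if minus else 1
        for length, op in rec.cigar:
            if op in "=X":
                for _ in range(length):
                    if pm.slots[t] == -1 and not pm.query_used[q]:
                        pm.slots[t] = q
                        base = qarr[q]
                        pm.alleles[t] = comp.get(base, b"N") if minus else base
                        pm.query_used[q] = True
                    t += 1
                    q += step
            elif op == "I":
                if minus:
                    lo, hi = q - length + 1, q + 1
                else:
                    lo, hi = q, q + length
                if not pm.query_used[lo:hi].any():
                    seg = query_seq[lo:hi]
                    pm.insertions.append((t, revcomp(seg) if minus else seg))
                    pm.query_used[lo:hi] = True
                q += step * length
            elif op == "D":
                if (pm.slots[t : t + length] == -1).all():
                    pm.slots[t : t + length] = -2
                    pm.deletions.append((t, t + length))
                t += length
    return pm
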