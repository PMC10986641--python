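"""Independent reference implementations used only to check the package.

These deliberately share no code with mhcforge: the affine-gap scorer is a
plain-Python three-matrix DP, and the placement oracle is a vectorized
unit-cost semi-global DP (free gaps on the target side).
"""

from __future__ import annotations

import numpy as np

NEG = -(10**9)


def gotoh_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> int:
    """Optimal global affine-gap alignment score, O(nm) plain Python."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        E[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        F[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N" and b[j - 1] != "N") else mismatch
            M[i][j] = max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s
            E[i][j] = max(
                E[i - 1][j] + gap_extend,
                M[i - 1][j] + gap_open + gap_extend,
                F[i - 1][j] + gap_open + gap_extend,
            )
            F[i][j] = max(
                F[i][j - 1] + gap_extend,
                M[i][j - 1] + gap_open + gap_extend,
                E[i][j - 1] + gap_open + gap_extend,
            )
    return max(M[n][m], E[n][m], F[n][m])


def semiglobal_distance(query: str, target: str) -> int:
    """Minimum unit-cost edit distance of query against any target substring.

    Row-wise DP over the query; the intra-row (horizontal) dependency is
    resolved with the running-minimum trick, so each row is a handful of
    vectorized numpy operations.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = len(t)
    prev = np.zeros(m + 1, dtype=np.int64)  # free start gap on target
    js = np.arange(m + 1)
    for i in range(1, len(q) + 1):
        sub = (q[i - 1] != t).astype(np.int64)
        vert_diag = np.minimum(prev[:-1] + sub, prev[1:] + 1)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = i
        cand[1:] = vert_diag
        prev = np.minimum.accumulate(cand - js) + js
    return int(prev.min())  # free end gap on target


_COMP = str.maketrans("ACGTN", "TGCAN")


def best_placement_distance(allele_seq: str, assembly_seq: str) -> int:
    """Best semi-global distance over both strands."""
    return min(
        semiglobal_distance(allele_seq, assembly_seq),
        semiglobal_distance(allele_seq.translate(_COMP)[::-1], assembly_seq),
    )
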