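"""Global pairwise alignment with affine gaps and free end gaps.

Needleman-Wunsch/Gotoh dynamic programming sized for the ~23 kb haplotype
alleles this package targets: the fill runs in a numba kernel with a
single packed uint8 traceback matrix (~n*m bytes), so two 23 kb sequences
align in a few seconds within ~0.6 GB.

Conventions
-----------
- A gap run of length k costs ``gap_open + k * gap_extend`` (the open
  penalty is a per-run surcharge).
- Terminal gap runs in either sequence are free ("free end gaps").
- Traceback ties prefer diagonal, then gap-in-B (a base of A over a gap),
  then gap-in-A; within a gap state, extension is preferred over opening.
- ``N`` (or any non-ACGT symbol mapped to N) never matches and scores as
  a mismatch.

Column states follow the reference-first convention: sequence A is the
reference; ``gap_in_B`` columns consume A only (deletions in B relative
to A), ``gap_in_A`` columns consume B only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["AlignmentScoring", "PairwiseAlignment", "global_align"]

_NEG = -1.0e30

MATCH, MISMATCH, GAP_IN_A, GAP_IN_B = "match", "mismatch", "gap_in_A", "gap_in_B"


@dataclass(frozen=True)
class AlignmentScoring:
    """Nucleotide scoring scheme (defaults: +5/-4, gap open -12, extend -2)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -12.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        for name in ("match", "mismatch", "gap_open", "gap_extend"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"scoring parameter {name} must be finite")


@dataclass
class PairwiseAlignment:
    """Columnar alignment of two sequences (A is the reference)."""

    a_gapped: str
    b_gapped: str
    score: float
    scoring: AlignmentScoring

    def __post_init__(self) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise ValueError("gapped sequences must have equal column counts")

    @property
    def n_columns(self) -> int:
        return len(self.a_gapped)

    def column_states(self) -> list[str]:
        """Per-column state; N vs anything counts as a mismatch."""
        states = []
        for ca, cb in zip(self.a_gapped, self.b_gapped):
            if ca == "-":
                states.append(GAP_IN_A)
            elif cb == "-":
                states.append(GAP_IN_B)
            elif ca == cb and ca != "N":
                states.append(MATCH)
            else:
                states.append(MISMATCH)
        return states

    def identity_mask(self) -> np.ndarray:
        """Boolean per column: identical (match) columns."""
        return np.array([s == MATCH for s in self.column_states()])

    def internal_range(self) -> tuple[int, int]:
        """Half-open column range [start, stop) excluding terminal free-end gap runs."""
        states = self.column_states()
        start, stop = 0, len(states)
        while start < stop and states[start] in (GAP_IN_A, GAP_IN_B):
            start += 1
        while stop > start and states[stop - 1] in (GAP_IN_A, GAP_IN_B):
            stop -= 1
        return start, stop


def _encode_for_alignment(seq: str, name: str) -> np.ndarray:
    s = seq.upper()
    if not s:
        raise ValueError(f"sequence {name} is empty")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence {name} contains non-nucleotide symbols: {sorted(bad)}")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0  # sentinel: never matches
    return arr


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    last_col = np.empty((n + 1, 3), dtype=np.float64)

    m_prev = np.empty(m + 1)
    ix_prev = np.empty(m + 1)
    iy_prev = np.empty(m + 1)
    m_cur = np.empty(m + 1)
    ix_cur = np.empty(m + 1)
    iy_cur = np.empty(m + 1)

    m_prev[0] = 0.0
    ix_prev[0] = _NEG
    iy_prev[0] = _NEG
    for j in range(1, m + 1):
        m_prev[j] = _NEG
        ix_prev[j] = _NEG
        iy_prev[j] = 0.0  # free leading gap in A
    last_col[0, 0] = m_prev[m]
    last_col[0, 1] = ix_prev[m]
    last_col[0, 2] = iy_prev[m]

    for i in range(1, n + 1):
        ai = a[i - 1]
        m_cur[0] = _NEG
        ix_cur[0] = 0.0  # free leading gap in B
        iy_cur[0] = _NEG
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 0) else mismatch
            # diagonal state: source is best of M/Ix/Iy at (i-1, j-1)
            src = 0
            best = m_prev[j - 1]
            if ix_prev[j - 1] > best:
                best = ix_prev[j - 1]
                src = 1
            if iy_prev[j - 1] > best:
                best = iy_prev[j - 1]
                src = 2
            m_cur[j] = best + s
            code = src
            # gap in B (consume A): from M or Ix at (i-1, j); ties extend
            v_open = m_prev[j] + gap_open + gap_ext
            v_ext = ix_prev[j] + gap_ext
            if v_open > v_ext:
                ix_cur[j] = v_open
            else:
                ix_cur[j] = v_ext
                code |= 4
            # gap in A (consume B): from M or Iy at (i, j-1); ties extend
            v_open = m_cur[j - 1] + gap_open + gap_ext
            v_ext = iy_cur[j - 1] + gap_ext
            if v_open > v_ext:
                iy_cur[j] = v_open
            else:
                iy_cur[j] = v_ext
                code |= 8
            tb[i, j] = code
        last_col[i, 0] = m_cur[m]
        last_col[i, 1] = ix_cur[m]
        last_col[i, 2] = iy_cur[m]
        m_prev, m_cur = m_cur, m_prev
        ix_prev, ix_cur = ix_cur, ix_prev
        iy_prev, iy_cur = iy_cur, iy_prev

    last_row = np.empty((m + 1, 3), dtype=np.float64)
    for j in range(m + 1):
        last_row[j, 0] = m_prev[j]
        last_row[j, 1] = ix_prev[j]
        last_row[j, 2] = iy_prev[j]
    return tb, last_col, last_row


def global_align(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide sequences, free end gaps.

    Deterministic: ties are broken diagonal > gap-in-B > gap-in-A, and at
    the free trailing end the full-span corner is preferred, then the
    shortest trailing gap in B, then the shortest trailing gap in A.
    """
    scoring = scoring or AlignmentScoring()
    a = _encode_for_alignment(seq_a, "A")
    b = _encode_for_alignment(seq_b, "B")
    sa, sb = seq_a.upper(), seq_b.upper()
    n, m = a.shape[0], b.shape[0]

    tb, last_col, last_row = _gotoh_fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )

    # candidate end cells in priority order; replace only on strict improvement
    best = _NEG
    start = (n, m, 0)
    for i in range(n, -1, -1):  # i == n first (corner), then shortest trailing gap in B
        for state in range(3):
            v = last_col[i, state]
            if v > best:
                best = v
                start = (i, m, state)
    for j in range(m - 1, -1, -1):
        for state in range(3):
            v = last_row[j, state]
            if v > best:
                best = v
                start = (n, j, state)

    i, j, state = start
    cols_a: list[str] = []
    cols_b: list[str] = []
    # free trailing gap columns
    for k in range(n, i, -1):
        cols_a.append(sa[k - 1])
        cols_b.append("-")
    for k in range(m, j, -1):
        cols_a.append("-")
        cols_b.append(sb[k - 1])

    while i > 0 and j > 0:
        code = tb[i, j]
        if state == 0:
            cols_a.append(sa[i - 1])
            cols_b.append(sb[j - 1])
            state = code & 3
            i -= 1
            j -= 1
        elif state == 1:
            cols_a.append(sa[i - 1])
            cols_b.append("-")
            state = 1 if (code & 4) else 0
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(sb[j - 1])
            state = 2 if (code & 8) else 0
            j -= 1
    # free leading gap columns
    for k in range(i, 0, -1):
        cols_a.append(sa[k - 1])
        cols_b.append("-")
    for k in range(j, 0, -1):
        cols_a.append("-")
        cols_b.append(sb[k - 1])

    return PairwiseAlignment(
        a_gapped="".join(reversed(cols_a)),
        b_gapped="".join(reversed(cols_b)),
        score=float(best),
        scoring=scoring,
    )
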