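"""Variant calling and divergence profiling on a pairwise alignment.

Variants are reported on the reference (first) sequence in 1-based
coordinates.  A maximal run of contiguous gap columns of one type is a
single indel event regardless of its length — mirroring how multi-bp
indels are counted as events, not columns.  Terminal free-end gap runs
are excluded from both variant calls and divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import GAP_IN_A, GAP_IN_B, MATCH, MISMATCH, PairwiseAlignment

__all__ = [
    "Snp",
    "Indel",
    "VariantSet",
    "SimilarityTrack",
    "call_variants",
    "percent_divergence",
    "window_similarity",
    "fixed_differences",
    "FixedDifferenceReport",
]


@dataclass(frozen=True)
class Snp:
    position: int  # 1-based on the reference (sequence A)
    ref: str
    alt: str


@dataclass(frozen=True)
class Indel:
    position: int  # 1-based reference position of the anchoring base before the event
    length: int
    kind: str  # "insertion" | "deletion" relative to the reference
    sequence: str  # inserted or deleted bases


@dataclass
class VariantSet:
    snps: list[Snp] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [s.position for s in self.snps]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("SNP positions must be strictly increasing")
        if any(i.length < 1 for i in self.indels):
            raise ValueError("indel length must be >= 1")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": s.position, "type": "snp", "ref": s.ref, "alt": s.alt, "length": 1}
            for s in self.snps
        ] + [
            {"position": i.position, "type": i.kind, "ref": "", "alt": i.sequence, "length": i.length}
            for i in self.indels
        ]
        df = pd.DataFrame(rows, columns=["position", "type", "ref", "alt", "length"])
        return df.sort_values(["position", "type"], kind="stable").reset_index(drop=True)


def call_variants(aln: PairwiseAlignment) -> VariantSet:
    """SNPs from mismatch columns, one indel per maximal gap run.

    Columns involving N produce no call.  Deletions (gap in B) anchor on
    the reference base preceding the run; insertions (gap in A) anchor on
    the last reference base before the run (0 if none).
    """
    states = aln.column_states()
    start, stop = aln.internal_range()
    snps: list[Snp] = []
    indels: list[Indel] = []
    ref_pos = aln.a_gapped[:start].replace("-", "")
    pos = len(ref_pos)  # reference bases consumed before the internal span

    c = start
    while c < stop:
        st = states[c]
        if st in (GAP_IN_A, GAP_IN_B):
            run_end = c
            while run_end < stop and states[run_end] == st:
                run_end += 1
            if st == GAP_IN_B:  # reference bases aligned to gaps: deletion in B
                seq = aln.a_gapped[c:run_end]
                indels.append(Indel(position=pos, length=run_end - c, kind="deletion", sequence=seq))
                pos += run_end - c
            else:  # bases only in B: insertion relative to the reference
                seq = aln.b_gapped[c:run_end]
                indels.append(Indel(position=pos, length=run_end - c, kind="insertion", sequence=seq))
            c = run_end
            continue
        if st == MISMATCH:
            ca, cb = aln.a_gapped[c], aln.b_gapped[c]
            if ca != "N" and cb != "N":
                snps.append(Snp(position=pos + 1, ref=ca, alt=cb))
        pos += 1
        c += 1
    return VariantSet(snps=snps, indels=indels)


def percent_divergence(aln: PairwiseAlignment, count_gap_columns: bool = True) -> float:
    """Percent non-identical internal columns.

    Gap columns count as non-identical by default (the convention under
    which indel gaps read as dissimilar stretches in a similarity plot);
    ``count_gap_columns=False`` restricts to substitution columns only.
    """
    states = aln.column_states()
    start, stop = aln.internal_range()
    internal = states[start:stop]
    if count_gap_columns:
        total = len(internal)
        diff = sum(s != MATCH for s in internal)
    else:
        total = sum(s in (MATCH, MISMATCH) for s in internal)
        diff = sum(s == MISMATCH for s in internal)
    if total == 0:
        raise ValueError("alignment has no internal columns")
    return 100.0 * diff / total


@dataclass
class SimilarityTrack:
    """Per-column percent identity in a centred window (default 500 bp)."""

    values: np.ndarray  # percent, one per alignment column
    window: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("similarity values must lie in [0, 100]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": np.arange(1, self.values.size + 1), "similarity_pct": self.values}
        )


def window_similarity(aln: PairwiseAlignment, w: int = 500) -> SimilarityTrack:
    """Percent identical columns in a window of w columns centred per column.

    Odd w gives a symmetric window; even w (like the 500 bp default)
    takes the extra column on the right.  Windows shrink at the alignment
    edges.  If w exceeds the alignment length the single global percent
    identity is broadcast to every column.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    ident = aln.identity_mask().astype(float)
    n = ident.size
    if w >= n:
        value = 100.0 * ident.sum() / n
        return SimilarityTrack(values=np.full(n, value), window=w)
    left = (w - 1) // 2
    right = w - 1 - left
    cum = np.concatenate([[0.0], np.cumsum(ident)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    values = 100.0 * (cum[hi] - cum[lo]) / (hi - lo)
    return SimilarityTrack(values=values, window=w)


@dataclass
class FixedDifferenceReport:
    n_fixed: int
    fixed_positions: list[int]  # 1-based site indices in the common frame
    variable_sites_a: list[int]
    variable_sites_b: list[int]

    @property
    def n_variable_a(self) -> int:
        return len(self.variable_sites_a)

    @property
    def n_variable_b(self) -> int:
        return len(self.variable_sites_b)


def _site_profile(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (consensus symbol index, minor allele frequency)."""
    n, length = haps.shape
    maf = np.empty(length)
    cons = np.empty(length, dtype=haps.dtype)
    for s in range(length):
        col = haps[:, s]
        symbols, counts = np.unique(col, return_counts=True)
        order = np.argsort(-counts, kind="stable")  # ties: first-seen (alphabetical) symbol
        cons[s] = symbols[order[0]]
        maf[s] = 1.0 - counts[order[0]] / n
    return cons, maf


def fixed_differences(
    group_a: list[str],
    group_b: list[str],
    maf_min: float = 0.25,
) -> FixedDifferenceReport:
    """Classify sites as fixed differences vs within-group variable sites.

    All haplotypes must share one coordinate frame (equal lengths).  A
    site is within-group variable when its minor allele frequency in that
    group is >= maf_min (inclusive threshold); a fixed difference requires
    both groups below the threshold with differing consensus bases.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 haplotypes")
    lengths = {len(h) for h in group_a} | {len(h) for h in group_b}
    if len(lengths) != 1:
        raise ValueError("haplotypes must share a common coordinate frame (equal lengths)")

    arr_a = np.array([list(h.upper()) for h in group_a])
    arr_b = np.array([list(h.upper()) for h in group_b])
    cons_a, maf_a = _site_profile(arr_a)
    cons_b, maf_b = _site_profile(arr_b)

    var_a = maf_a >= maf_min
    var_b = maf_b >= maf_min
    fixed = (~var_a) & (~var_b) & (cons_a != cons_b)

    return FixedDifferenceReport(
        n_fixed=int(fixed.sum()),
        fixed_positions=list(np.flatnonzero(fixed) + 1),
        variable_sites_a=list(np.flatnonzero(var_a) + 1),
        variable_sites_b=list(np.flatnonzero(var_b) + 1),
    )
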