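"""Felsenstein pruning likelihood on the fixed 3-taxon clock tree.

Topology: ((ingroup_a, ingroup_b) at t_split, outgroup) rooted at the
calibration node at t_cal.  Under a strict clock with rate r
(substitutions per site per My), branch lengths in substitutions per
site are r*t_split for each ingroup tip, r*(t_cal - t_split) for the
internal branch, and r*t_cal for the outgroup tip.

Alignment columns containing gaps or ambiguous bases are excluded; site
patterns are compressed to at most 64 distinct ACGT triples, so the
likelihood cost is independent of alignment length after the first pass.
"""

from __future__ import annotations

import numpy as np

from .hky import HkyModel, encode, transition_matrix


def site_patterns(seq_a: str | np.ndarray, seq_b: str | np.ndarray,
                  seq_out: str | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress a 3-sequence alignment to (patterns, counts).

    patterns is (k, 3) int with base codes; columns with any non-ACGT
    symbol (gap, N) are dropped.
    """
    cols = []
    for s in (seq_a, seq_b, seq_out):
        arr = encode(s) if isinstance(s, str) else np.asarray(s)
        cols.append(arr)
    a, b, o = cols
    if not (a.shape == b.shape == o.shape):
        raise ValueError("aligned sequences must have equal length")
    keep = (a >= 0) & (b >= 0) & (o >= 0)
    a, b, o = a[keep], b[keep], o[keep]
    if a.size == 0:
        return np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = a.astype(np.int64) * 16 + b * 4 + o
    uniq, counts = np.unique(codes, return_counts=True)
    patterns = np.stack([uniq // 16, (uniq // 4) % 4, uniq % 4], axis=1)
    return patterns, counts


def likelihood_3taxon(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    seq_out: str | np.ndarray,
    t_split: float,
    t_cal: float,
    clock_rate: float,
    model: HkyModel,
) -> float:
    """Log-likelihood of the 3-taxon alignment under HKY and a strict clock.

    Empty alignments (or all-gap/ambiguous ones) return 0.0, so the MCMC
    degenerates to prior sampling.
    """
    patterns, counts = site_patterns(seq_a, seq_b, seq_out)
    return loglik_from_patterns(patterns, counts, t_split, t_cal, clock_rate, model)


def loglik_from_patterns(
    patterns: np.ndarray,
    counts: np.ndarray,
    t_split: float,
    t_cal: float,
    clock_rate: float,
    model: HkyModel,
) -> float:
    for name, v in (("t_split", t_split), ("t_cal", t_cal), ("clock_rate", clock_rate)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if not (0 <= t_split < t_cal):
        raise ValueError(f"need 0 <= t_split < t_cal, got {t_split}, {t_cal}")
    if clock_rate <= 0:
        raise ValueError(f"clock_rate must be > 0, got {clock_rate}")
    if len(patterns) == 0:
        return 0.0

    p_tip = transition_matrix(model, clock_rate * t_split)        # ancestor -> each ingroup tip
    p_int = transition_matrix(model, clock_rate * (t_cal - t_split))  # root -> ingroup ancestor
    p_out = transition_matrix(model, clock_rate * t_cal)          # root -> outgroup
    pi = model.pi

    a, b, o = patterns[:, 0], patterns[:, 1], patterns[:, 2]
    # partial likelihood at the ingroup ancestor, shape (k, 4) over its state x
    l_anc = p_tip[:, a].T * p_tip[:, b].T
    # root: sum over root state z of pi_z * P_out[z, o] * sum_x P_int[z, x] l_anc[x]
    inner = l_anc @ p_int.T            # (k, 4) over root state z
    site_l = np.einsum("z,kz,kz->k", pi, inner, p_out[:, o].T)
    return float(np.dot(counts, np.log(site_l)))
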