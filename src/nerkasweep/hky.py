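"""HKY85 nucleotide substitution model.

The HKY model allows unequal equilibrium base frequencies (pi_A, pi_C,
pi_G, pi_T) and a transition/transversion rate ratio kappa.  The rate
matrix is normalised so that one unit of branch length equals one
expected substitution per site; all distances returned here are in
substitutions per site.

Bases are encoded internally as integers 0=A, 1=C, 2=G, 3=T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# purine/pyrimidine class of each base (A,G purines; C,T pyrimidines)
_PURINE = np.array([True, False, True, False])


@dataclass(frozen=True)
class HkyModel:
    """HKY85 model parameters.

    kappa : transition/transversion rate ratio (>0).
    base_freqs : equilibrium frequencies (pi_A, pi_C, pi_G, pi_T), positive,
        summing to 1 within 1e-12.
    """

    kappa: float = 3.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError(f"kappa must be positive and finite, got {self.kappa}")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("base_freqs must be four positive numbers")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"base_freqs must sum to 1, got {freqs.sum()!r}")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Normalised instantaneous rate matrix Q (rows sum to zero).

        Q[i, j] = beta * pi_j for transversions and kappa * beta * pi_j for
        transitions, with beta chosen so the mean substitution rate at
        stationarity is 1.
        """
        pi = self.pi
        kappa = self.kappa
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j] * (kappa if _PURINE[i] == _PURINE[j] else 1.0)
                q[i, j] = rate
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(q)))
        return q / mean_rate


def _rate_scale(model: HkyModel) -> float:
    """beta such that mean rate of the unscaled HKY matrix is 1."""
    pi = model.pi
    pi_r = pi[0] + pi[2]
    pi_y = pi[1] + pi[3]
    mean = 2.0 * model.kappa * (pi[0] * pi[2] + pi[1] * pi[3]) + 2.0 * pi_r * pi_y
    return 1.0 / mean


def transition_matrix(model: HkyModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) in closed form (TN93 formulas with equal transition rates).

    `t` is branch length in expected substitutions per site.
    """
    if t < 0 or not np.isfinite(t):
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    pi = model.pi
    beta = _rate_scale(model)
    alpha = model.kappa * beta
    pi_class = np.where(_PURINE, pi[0] + pi[2], pi[1] + pi[3])  # class freq of each base

    e_beta = np.exp(-beta * t)
    # class-specific decay: exp(-t * (class_freq * alpha + other_class_freq * beta))
    e_class = np.exp(-t * (pi_class * alpha + (1.0 - pi_class) * beta))

    p = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            pj, cj = pi[j], pi_class[j]
            if i == j:
                p[i, j] = pj + pj * ((1.0 - cj) / cj) * e_beta + ((cj - pj) / cj) * e_class[j]
            elif _PURINE[i] == _PURINE[j]:
                p[i, j] = pj + pj * ((1.0 - cj) / cj) * e_beta - (pj / cj) * e_class[j]
            else:
                p[i, j] = pj * (1.0 - e_beta)
    return p


def _transition_matrix_deriv(model: HkyModel, t: float) -> np.ndarray:
    """dP(t)/dt, analytic (P is affine in two exponentials)."""
    pi = model.pi
    beta = _rate_scale(model)
    alpha = model.kappa * beta
    pi_class = np.where(_PURINE, pi[0] + pi[2], pi[1] + pi[3])

    r_class = pi_class * alpha + (1.0 - pi_class) * beta
    e_beta = np.exp(-beta * t)
    e_class = np.exp(-t * r_class)

    d = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            pj, cj = pi[j], pi_class[j]
            if i == j:
                d[i, j] = -beta * pj * ((1.0 - cj) / cj) * e_beta - r_class[j] * ((cj - pj) / cj) * e_class[j]
            elif _PURINE[i] == _PURINE[j]:
                d[i, j] = -beta * pj * ((1.0 - cj) / cj) * e_beta + r_class[j] * (pj / cj) * e_class[j]
            else:
                d[i, j] = beta * pj * e_beta
    return d


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as integers; any other symbol maps to -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def pair_counts(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> np.ndarray:
    """4x4 matrix of aligned-site counts; sites with non-ACGT symbols dropped."""
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    counts = np.zeros((4, 4), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    return counts


_SATURATION_BOUND = 50.0


def hky_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray, model: HkyModel) -> float:
    """Maximum-likelihood pairwise distance (subs/site) under a fixed HKY model.

    Maximises sum_ij N_ij log(pi_i P_ij(t)) over t by solving dl/dt = 0
    with a bracketing root finder on the analytic derivative.  Reduces to
    the JC69 closed form at equal frequencies with kappa = 1, and to the
    K80 closed form at equal frequencies with kappa fixed at its K80
    estimate.

    Saturated pairs (likelihood still increasing at t = 50) return +inf.
    """
    counts = pair_counts(seq_a, seq_b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no comparable A/C/G/T sites")
    n_diff = total - np.trace(counts)
    if n_diff == 0:
        return 0.0

    def dll(t: float) -> float:
        p = transition_matrix(model, t)
        dp = _transition_matrix_deriv(model, t)
        return float(np.sum(counts * dp / p))

    lo = 1e-12
    if dll(lo) <= 0:  # optimum at the boundary: effectively zero distance
        return 0.0
    if dll(_SATURATION_BOUND) > 0:
        return float("inf")
    return float(brentq(dll, lo, _SATURATION_BOUND, xtol=1e-14, rtol=8.9e-16))


def jc69_distance(p_diff: float) -> float:
    """JC69 closed-form distance from a proportion of differing sites."""
    arg = 1.0 - 4.0 * p_diff / 3.0
    if arg <= 0:
        return float("inf")
    return -0.75 * np.log(arg)


def k80_distance(p_transition: float, p_transversion: float) -> tuple[float, float]:
    """K80 closed-form (distance, kappa_hat) from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p_transition - p_transversion
    w2 = 1.0 - 2.0 * p_transversion
    if w1 <= 0 or w2 <= 0:
        return float("inf"), float("nan")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    alpha_t = -0.5 * np.log(w1) + 0.25 * np.log(w2)
    beta_t = -0.25 * np.log(w2)
    kappa_hat = alpha_t / beta_t if beta_t > 0 else float("inf")
    return float(d), float(kappa_hat)
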