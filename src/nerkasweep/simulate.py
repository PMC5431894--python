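"""Synthetic haplotype and genotype generation.

Emulates the generative structure the downstream analyses assume: two
haplotype alleles ("shore" and "stream") descended from a common
ancestor t_split My ago under an HKY substitution process with a
deletion-only indel process, an outgroup lineage splitting t_cal My ago
at the calibration node, within-group site polymorphism, and population
genotype tables drawn binomially at specified G-allele frequencies
(Hardy-Weinberg sampling).

The default scenario mirrors the study region: a 22,773 bp locus, a
3.8 My allele split calibrated against an 11.4 My outgroup, a strict
clock rate and indel rate chosen so that the expected numbers of fixed
substitutions (~158), indel events (~23) and gap columns (~880) between
the two alleles match the observed sweep region, and a within-group
polymorphism probability giving ~10 variable sites per allele class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hky import BASES, HkyModel, transition_matrix

__all__ = [
    "SimScenario",
    "PopulationSpec",
    "simulate_allele_divergence",
    "simulate_within_group_haplotypes",
    "simulate_genotype_table",
]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for haplotype divergence and population sampling.

    Times are in millions of years (My); clock_rate in substitutions per
    site per My; indel_rate in deletion events per site per My.  Indel
    lengths are geometric with success probability ``indel_length_p``,
    capped at ``indel_length_max`` bp.
    """

    seq_length: int = 22_773
    t_split: float = 3.8
    t_cal: float = 11.4
    clock_rate: float = 9.2e-4
    kappa: float = 3.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    indel_rate: float = 1.33e-4
    indel_length_p: float = 0.026
    indel_length_max: int = 400
    n_haplotypes_per_group: int = 8
    theta_within: float = 4.4e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        for name in ("t_split", "t_cal", "clock_rate", "indel_rate", "theta_within"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not self.t_split < self.t_cal:
            raise ValueError(f"need t_split < t_cal, got {self.t_split} >= {self.t_cal}")
        if not (0 <= self.theta_within <= 1):
            raise ValueError("theta_within must be in [0, 1]")
        if not (0 < self.indel_length_p <= 1):
            raise ValueError("indel_length_p must be in (0, 1]")
        freqs = np.asarray(self.base_freqs)
        if abs(freqs.sum() - 1.0) > 1e-12 or np.any(freqs <= 0):
            raise ValueError("base_freqs must be positive and sum to 1")
        HkyModel(kappa=self.kappa, base_freqs=self.base_freqs)  # validates kappa

    @property
    def model(self) -> HkyModel:
        return HkyModel(kappa=self.kappa, base_freqs=self.base_freqs)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    ecotype_label: str  # "shore" | "stream"
    n_individuals: int
    p_g: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("population name must be nonempty")
        if self.ecotype_label not in ("shore", "stream"):
            raise ValueError(f"ecotype_label must be shore or stream, got {self.ecotype_label!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.p_g <= 1.0):
            raise ValueError(f"p_G must be in [0, 1], got {self.p_g}")


def _evolve_substitutions(seq: np.ndarray, branch_len: float, model: HkyModel,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint-sample each site from P(branch_len); return (new_seq, changed_idx)."""
    if branch_len == 0.0:
        return seq.copy(), np.empty(0, dtype=np.int64)
    p = transition_matrix(model, branch_len)
    cum = np.cumsum(p, axis=1)
    u = rng.random(seq.size)
    new = (u[:, None] > cum[seq]).sum(axis=1).astype(seq.dtype)
    return new, np.flatnonzero(new != seq)


def _apply_deletions(seq: np.ndarray, t: float, scenario: SimScenario,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Poisson-many deletions along a branch; returns (seq, [(pos_1based, length)]).

    Positions are 1-based in the coordinates of the sequence entering the
    branch (before any of this branch's deletions are applied).
    """
    n_events = rng.poisson(scenario.indel_rate * t * seq.size)
    if n_events == 0:
        return seq.copy(), []
    starts = np.sort(rng.integers(0, seq.size, size=n_events))[::-1]  # apply right-to-left
    lengths = np.minimum(rng.geometric(scenario.indel_length_p, size=n_events),
                         scenario.indel_length_max)
    events = []
    out = seq.copy()
    for start, length in zip(starts, lengths):
        length = int(min(length, out.size - start))
        if length <= 0:
            continue
        out = np.delete(out, slice(int(start), int(start) + length))
        events.append((int(start) + 1, length))
    return out, sorted(events)


def _evolve_branch(seq, branch_name, time, scenario, rng, events):
    model = scenario.model
    new, changed = _evolve_substitutions(seq, scenario.clock_rate * time, model, rng)
    for pos in changed:
        events.append(
            {"branch": branch_name, "event": "substitution", "position": int(pos) + 1,
             "length": 1, "from": BASES[seq[pos]], "to": BASES[new[pos]]}
        )
    new, dels = _apply_deletions(new, time, scenario, rng)
    for pos, length in dels:
        events.append(
            {"branch": branch_name, "event": "deletion", "position": pos,
             "length": length, "from": "", "to": ""}
        )
    return new


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[i] for i in seq)


def simulate_allele_divergence(
    scenario: SimScenario, seed: int | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate shore, stream and outgroup sequences plus the true event log.

    The ancestral sequence at the calibration node is drawn i.i.d. from
    the equilibrium base frequencies.  The outgroup evolves for t_cal;
    the ingroup ancestor evolves for t_cal - t_split before splitting
    into the shore and stream lineages, which each evolve independently
    for t_split.  Substitutions are endpoint-sampled from the HKY
    transition matrix; deletions are Poisson along each branch.

    Event-log positions are 1-based in the coordinates of the sequence
    entering the branch on which the event occurred.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    pi = np.asarray(scenario.base_freqs)
    root = rng.choice(4, size=scenario.seq_length, p=pi).astype(np.int8)

    events: list[dict] = []
    outgroup = _evolve_branch(root, "root->outgroup", scenario.t_cal, scenario, rng, events)
    anc = _evolve_branch(root, "root->ingroup_ancestor", scenario.t_cal - scenario.t_split,
                         scenario, rng, events)
    shore = _evolve_branch(anc, "ancestor->shore", scenario.t_split, scenario, rng, events)
    stream = _evolve_branch(anc, "ancestor->stream", scenario.t_split, scenario, rng, events)

    log = pd.DataFrame(events, columns=["branch", "event", "position", "length", "from", "to"])
    seqs = {
        "shore": _decode(shore),
        "stream": _decode(stream),
        "outgroup": _decode(outgroup),
        "ancestor": _decode(anc),
    }
    return seqs, log


def simulate_within_group_haplotypes(
    group_consensus: str, n: int, theta_within: float, seed: int = 0
) -> list[str]:
    """n haplotypes around a consensus with site-independent polymorphism.

    Each site is polymorphic with probability theta_within; a polymorphic
    site carries one alternative base (uniform over the other three) at a
    uniform random minor count in {1, ..., n-1} assigned to a random
    subset of haplotypes.
    """
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if not (0.0 <= theta_within <= 1.0):
        raise ValueError(f"theta_within must be in [0, 1], got {theta_within}")
    rng = np.random.default_rng(seed)
    length = len(group_consensus)
    haps = np.array([list(group_consensus)] * n)
    poly_sites = np.flatnonzero(rng.random(length) < theta_within)
    for site in poly_sites:
        ref = haps[0, site]
        alt = rng.choice([b for b in BASES if b != ref])
        k = int(rng.integers(1, n))
        carriers = rng.choice(n, size=k, replace=False)
        haps[carriers, site] = alt
    return ["".join(row) for row in haps]


def simulate_genotype_table(
    pop_specs: list[PopulationSpec], seed: int = 0, missing_rate: float = 0.0
) -> pd.DataFrame:
    """Draw a genotype table under Hardy-Weinberg sampling.

    Each individual's genotype is two independent Bernoulli(p_G) allele
    draws; ``missing_rate`` optionally replaces genotypes with NN.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in pop_specs:
        n_g_alleles = rng.binomial(2, spec.p_g, size=spec.n_individuals)
        miss = rng.random(spec.n_individuals) < missing_rate
        for i, (k, is_missing) in enumerate(zip(n_g_alleles, miss)):
            genotype = "NN" if is_missing else ("TT", "GT", "GG")[k]
            rows.append(
                {
                    "sample_id": f"{spec.name}_{i + 1:03d}",
                    "population": spec.name,
                    "ecotype": spec.ecotype_label,
                    "genotype": genotype,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "population", "ecotype", "genotype"])
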