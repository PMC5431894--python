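"""Diagnostic-SNP genotype analysis for shore/stream ecotype populations.

A genotype table is a pandas DataFrame with columns
``sample_id, population, ecotype, genotype`` where genotype is one of
GG, GT, TT, NN (NN = missing) at the diagnostic biallelic G/T SNP, and
ecotype is the field-observed label ("shore" or "stream").

The Mendelian assignment rule is GG -> shore, GT or TT -> stream; its
accuracy against the observed labels is the headline diagnostic of how
cleanly the locus separates reproductive ecotypes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VALID_GENOTYPES",
    "validate_genotype_table",
    "FreqSummary",
    "summarize_frequencies",
    "mendelian_assign",
    "AssignmentReport",
    "assignment_accuracy",
    "FstResult",
    "fst_pair",
    "ld_r2",
]

VALID_GENOTYPES = ("GG", "GT", "TT", "NN")
TABLE_COLUMNS = ("sample_id", "population", "ecotype", "genotype")


def validate_genotype_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("genotype table is empty")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"genotype table lacks columns: {sorted(missing)}")
    bad = set(table["genotype"]) - set(VALID_GENOTYPES)
    if bad:
        raise ValueError(f"invalid genotype symbols: {sorted(bad)}")
    if (table["population"].astype(str).str.len() == 0).any():
        raise ValueError("population names must be nonempty")
    return table


@dataclass(frozen=True)
class FreqSummary:
    """Per-population allele/genotype frequency summary (missing excluded)."""

    population: str
    n: int
    n_gg: int
    n_gt: int
    n_tt: int

    @property
    def p_g(self) -> float:
        return (2 * self.n_gg + self.n_gt) / (2 * self.n)

    @property
    def p_t(self) -> float:
        return 1.0 - self.p_g

    @property
    def genotype_counts(self) -> tuple[int, int, int]:
        return (self.n_gg, self.n_gt, self.n_tt)


def summarize_frequencies(table: pd.DataFrame) -> list[FreqSummary]:
    """One FreqSummary per population; NN genotypes excluded from n.

    Populations whose genotypes are all missing are excluded from the
    output (they have no defined allele frequency).
    """
    validate_genotype_table(table)
    out = []
    for pop, grp in table.groupby("population", sort=False):
        counts = grp["genotype"].value_counts()
        n_gg = int(counts.get("GG", 0))
        n_gt = int(counts.get("GT", 0))
        n_tt = int(counts.get("TT", 0))
        n = n_gg + n_gt + n_tt
        if n == 0:
            continue
        out.append(FreqSummary(population=str(pop), n=n, n_gg=n_gg, n_gt=n_gt, n_tt=n_tt))
    return out


def mendelian_assign(genotype: str) -> str:
    """GG -> shore, GT/TT -> stream, NN -> unassigned."""
    if genotype == "GG":
        return "shore"
    if genotype in ("GT", "TT"):
        return "stream"
    if genotype == "NN":
        return "unassigned"
    raise ValueError(f"unknown genotype symbol: {genotype!r}")


@dataclass
class AssignmentReport:
    """Mendelian-rule concordance with observed ecotype labels."""

    per_population: pd.DataFrame  # population, ecotype, n, correct, incorrect
    gg_in_stream: int
    gt_in_shore: int
    tt_in_shore: int
    n_stream: int
    n_shore: int

    @property
    def correct(self) -> int:
        return int(self.per_population["correct"].sum())

    @property
    def incorrect(self) -> int:
        return int(self.per_population["incorrect"].sum())

    @property
    def accuracy_pct(self) -> float:
        total = self.correct + self.incorrect
        return 100.0 * self.correct / total


def assignment_accuracy(table: pd.DataFrame, systems: list[str]) -> AssignmentReport:
    """Apply the Mendelian rule within the named populations.

    Unassigned (NN) individuals are excluded from all denominators.
    Pooled miscall classes are reported: GG among stream-labelled fish,
    GT and TT among shore-labelled fish.
    """
    validate_genotype_table(table)
    if not systems:
        raise ValueError("empty population list")
    present = set(table["population"])
    absent = [s for s in systems if s not in present]
    if absent:
        raise ValueError(f"populations not in table: {absent}")

    sub = table[table["population"].isin(systems) & (table["genotype"] != "NN")].copy()
    sub["predicted"] = sub["genotype"].map(mendelian_assign)
    sub["is_correct"] = sub["predicted"] == sub["ecotype"]

    rows = []
    for pop in systems:
        grp = sub[sub["population"] == pop]
        rows.append(
            {
                "population": pop,
                "ecotype": grp["ecotype"].iloc[0] if len(grp) else "",
                "n": len(grp),
                "correct": int(grp["is_correct"].sum()),
                "incorrect": int((~grp["is_correct"]).sum()),
            }
        )
    stream = sub[sub["ecotype"] == "stream"]
    shore = sub[sub["ecotype"] == "shore"]
    return AssignmentReport(
        per_population=pd.DataFrame(rows),
        gg_in_stream=int((stream["genotype"] == "GG").sum()),
        gt_in_shore=int((shore["genotype"] == "GT").sum()),
        tt_in_shore=int((shore["genotype"] == "TT").sum()),
        n_stream=len(stream),
        n_shore=len(shore),
    )


@dataclass
class FstResult:
    estimator: str  # "nei_gst" | "weir_cockerham"
    value: float
    components: dict[str, float]
    undefined: bool = False


def _nei_gst(freq_a: FreqSummary, freq_b: FreqSummary) -> FstResult:
    # unweighted means: classical GST with equal population weights
    h_s = (2 * freq_a.p_g * freq_a.p_t + 2 * freq_b.p_g * freq_b.p_t) / 2.0
    p_bar = (freq_a.p_g + freq_b.p_g) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return FstResult("nei_gst", float("nan"), {"H_T": 0.0, "H_S": 0.0}, undefined=True)
    return FstResult("nei_gst", 1.0 - h_s / h_t, {"H_T": h_t, "H_S": h_s})


def _weir_cockerham(freq_a: FreqSummary, freq_b: FreqSummary) -> FstResult:
    """Two-population variance components a (among), b (within, between
    individuals) and c (within individuals) from genotype counts."""
    r = 2
    n_i = np.array([freq_a.n, freq_b.n], dtype=float)
    p_i = np.array([freq_a.p_g, freq_b.p_g])
    h_i = np.array([freq_a.n_gt / freq_a.n, freq_b.n_gt / freq_b.n])  # observed het

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    comps = {"a": float(a), "b": float(b), "c": float(c)}
    if denom == 0.0:
        return FstResult("weir_cockerham", float("nan"), comps, undefined=True)
    return FstResult("weir_cockerham", float(a / denom), comps)


def fst_pair(freq_a: FreqSummary, freq_b: FreqSummary, estimator: str = "nei_gst") -> FstResult:
    """Pairwise FST between two populations at the diagnostic SNP.

    ``nei_gst`` uses unweighted heterozygosity means (classical GST, in
    [0, 1]); ``weir_cockerham`` uses the 1984 variance components from
    genotype counts and may be slightly negative (reported unclamped).
    Both populations fixed for the same allele leave FST undefined
    (NaN, flagged).
    """
    if freq_a.n < 1 or freq_b.n < 1:
        raise ValueError("both populations need n >= 1")
    if estimator == "nei_gst":
        return _nei_gst(freq_a, freq_b)
    if estimator == "weir_cockerham":
        return _weir_cockerham(freq_a, freq_b)
    raise ValueError(f"unknown estimator: {estimator!r}")


def ld_r2(haplotypes: list[str] | np.ndarray) -> pd.DataFrame:
    """Pairwise r-squared between biallelic sites over phased haplotypes.

    ``haplotypes`` is a list of equal-length strings (or a 2D array) with
    one row per haplotype and one column per site.  Returns a DataFrame
    with columns site_i, site_j (1-based), r2; monomorphic sites yield
    NaN, flagged in the ``defined`` column.
    """
    arr = np.array([list(h) for h in haplotypes]) if not isinstance(haplotypes, np.ndarray) else haplotypes
    n, n_sites = arr.shape
    if n_sites < 2:
        raise ValueError("need at least 2 sites")

    # encode each site 0/1 on its two alleles; None for monomorphic/multiallelic
    coded: list[np.ndarray | None] = []
    for s in range(n_sites):
        alleles = sorted(set(arr[:, s]))
        if len(alleles) == 1:
            coded.append(None)
        elif len(alleles) == 2:
            coded.append((arr[:, s] == alleles[1]).astype(float))
        else:
            raise ValueError(f"site {s + 1} is not biallelic: {alleles}")

    rows = []
    for i, j in itertools.combinations(range(n_sites), 2):
        xi, xj = coded[i], coded[j]
        if xi is None or xj is None:
            rows.append({"site_i": i + 1, "site_j": j + 1, "r2": float("nan"), "defined": False})
            continue
        p_i, p_j = xi.mean(), xj.mean()
        d = (xi * xj).mean() - p_i * p_j
        r2 = d * d / (p_i * (1 - p_i) * p_j * (1 - p_j))
        rows.append({"site_i": i + 1, "site_j": j + 1, "r2": float(r2), "defined": True})
    return pd.DataFrame(rows)


def full_linkage(r2_table: pd.DataFrame, tol: float = 1e-12) -> bool:
    """True when every defined site pair has r2 == 1 (within tol)."""
    defined = r2_table[r2_table["defined"]]
    if defined.empty:
        return False
    return bool((defined["r2"] >= 1.0 - tol).all())
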