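"""Synthetic-data generator: zero-rate identities, seed determinism,
HKY divergence calibration and Poisson indel counts."""

import numpy as np
import pytest
from scipy.linalg import expm

from nerkasweep.hky import BASE_INDEX
from nerkasweep.simulate import (
    PopulationSpec,
    SimScenario,
    simulate_allele_divergence,
    simulate_genotype_table,
    simulate_within_group_haplotypes,
)


def test_zero_rates_give_identical_sequences():
    sc = SimScenario(seq_length=500, clock_rate=0.0, indel_rate=0.0, seed=3)
    seqs, log = simulate_allele_divergence(sc)
    assert seqs["shore"] == seqs["stream"] == seqs["outgroup"] == seqs["ancestor"]
    assert log.empty


def test_no_indels_conserves_length():
    sc = SimScenario(seq_length=1234, indel_rate=0.0, seed=5)
    seqs, _ = simulate_allele_divergence(sc)
    assert all(len(s) == 1234 for s in seqs.values())


def test_seed_determinism_byte_identical():
    sc = SimScenario(seq_length=800, seed=11)
    s1, log1 = simulate_allele_divergence(sc)
    s2, log2 = simulate_allele_divergence(sc)
    assert s1 == s2
    assert log1.equals(log2)


def test_different_seeds_differ():
    sc = SimScenario(seq_length=800, seed=11)
    s1, _ = simulate_allele_divergence(sc)
    s2, _ = simulate_allele_divergence(sc, seed=12)
    assert s1["shore"] != s2["shore"]


def test_pairwise_divergence_matches_hky_expectation():
    """Mean shore-stream divergence over replicates vs the matrix-exponential
    expectation 1 - sum_i pi_i P_ii(2 t r), within 3 standard errors."""
    L, rate, t = 10_000, 9.2e-4, 3.8
    sc = SimScenario(seq_length=L, clock_rate=rate, indel_rate=0.0, t_split=t)
    p = expm(sc.model.rate_matrix() * (2 * t * rate))
    expected = 1.0 - float(np.dot(sc.model.pi, np.diag(p)))

    diffs = []
    for rep in range(20):
        seqs, _ = simulate_allele_divergence(sc, seed=1000 + rep)
        d = sum(a != b for a, b in zip(seqs["shore"], seqs["stream"])) / L
        diffs.append(d)
    mean = np.mean(diffs)
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(mean - expected) < 3 * se + 1e-12


def test_event_log_substitution_positions_are_truthful_without_indels():
    sc = SimScenario(seq_length=5000, indel_rate=0.0, seed=21)
    seqs, log = simulate_allele_divergence(sc)
    shore_subs = log[(log["branch"] == "ancestor->shore") & (log["event"] == "substitution")]
    anc, shore = seqs["ancestor"], seqs["shore"]
    changed = {i + 1 for i in range(len(anc)) if anc[i] != shore[i]}
    assert set(shore_subs["position"]) == changed


def test_indel_event_count_is_poisson():
    """Deletion count on the outgroup branch across replicates vs Poisson(rate*t*L)."""
    L, rate, t_cal = 5000, 4e-4, 11.4
    sc = SimScenario(seq_length=L, clock_rate=0.0, indel_rate=rate, t_cal=t_cal)
    lam = rate * t_cal * L
    counts = []
    for rep in range(30):
        _, log = simulate_allele_divergence(sc, seed=2000 + rep)
        counts.append(((log["branch"] == "root->outgroup") & (log["event"] == "deletion")).sum())
    mean = np.mean(counts)
    se = np.sqrt(lam / len(counts))  # Poisson variance = lambda
    assert abs(mean - lam) < 3 * se


def test_indel_lengths_capped():
    sc = SimScenario(seq_length=5000, clock_rate=0.0, indel_rate=2e-3,
                     indel_length_p=0.005, indel_length_max=50, seed=9)
    _, log = simulate_allele_divergence(sc)
    dels = log[log["event"] == "deletion"]
    assert len(dels) > 0
    assert dels["length"].max() <= 50


def test_scenario_validation():
    with pytest.raises(ValueError):
        SimScenario(seq_length=0)
    with pytest.raises(ValueError):
        SimScenario(t_split=12.0, t_cal=11.4)
    with pytest.raises(ValueError):
        SimScenario(clock_rate=-1e-3)
    with pytest.raises(ValueError):
        SimScenario(base_freqs=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimScenario(theta_within=1.5)


class TestWithinGroup:
    def test_theta_zero_gives_identical_haplotypes(self):
        haps = simulate_within_group_haplotypes("ACGT" * 50, 8, 0.0, seed=1)
        assert len(haps) == 8
        assert all(h == "ACGT" * 50 for h in haps)

    def test_theta_one_makes_every_site_polymorphic(self):
        haps = simulate_within_group_haplotypes("A" * 100, 4, 1.0, seed=2)
        arr = np.array([list(h) for h in haps])
        n_poly = sum(len(set(arr[:, s])) > 1 for s in range(100))
        assert n_poly == 100

    def test_intermediate_theta_within_binomial_bounds(self):
        theta, L = 0.3, 2000
        haps = simulate_within_group_haplotypes("C" * L, 6, theta, seed=3)
        arr = np.array([list(h) for h in haps])
        n_poly = sum(len(set(arr[:, s])) > 1 for s in range(L))
        sigma = np.sqrt(L * theta * (1 - theta))
        assert abs(n_poly - L * theta) < 3 * sigma

    def test_seed_determinism(self):
        h1 = simulate_within_group_haplotypes("ACGT" * 25, 2, 0.5, seed=7)
        h2 = simulate_within_group_haplotypes("ACGT" * 25, 2, 0.5, seed=7)
        assert h1 == h2

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_within_group_haplotypes("ACGT", 1, 0.1)
        with pytest.raises(ValueError):
            simulate_within_group_haplotypes("ACGT", 4, 1.2)


class TestGenotypeTable:
    def test_fixed_population_all_gg(self):
        spec = PopulationSpec("fixed", "shore", 20, 1.0)
        table = simulate_genotype_table([spec], seed=0)
        assert (table["genotype"] == "GG").all()

    def test_hardy_weinberg_proportions(self):
        spec = PopulationSpec("hw", "shore", 10_000, 0.5)
        table = simulate_genotype_table([spec], seed=1)
        counts = table["genotype"].value_counts()
        n = len(table)
        for geno, expected_p in (("GG", 0.25), ("GT", 0.5), ("TT", 0.25)):
            sigma = np.sqrt(n * expected_p * (1 - expected_p))
            assert abs(counts[geno] - n * expected_p) < 3 * sigma

    def test_table1_preset_expected_frequencies(self):
        from nerkasweep.fixtures import load_table1, table1_population_specs

        fixture = load_table1()
        specs = table1_population_specs(fixture)
        by_name = {s.name: s for s in specs}
        for _, row in fixture.rows.iterrows():
            assert by_name[row["population"]].p_g == pytest.approx(row["p_G"])
            assert by_name[row["population"]].n_individuals == row["n"]
        # simulated allele frequencies converge on the printed values
        big = [PopulationSpec(s.name, s.ecotype_label, 5000, s.p_g)
               for s in specs if s.name in ("Okanagan Lake", "Mission Creek")]
        table = simulate_genotype_table(big, seed=2)
        from nerkasweep.genotypes import summarize_frequencies

        for f in summarize_frequencies(table):
            target = by_name[f.population].p_g
            sigma = np.sqrt(target * (1 - target) / (2 * 5000))
            assert abs(f.p_g - target) < 4 * sigma + 1e-9

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec("x", "shore", 10, 1.2)
        with pytest.raises(ValueError):
            PopulationSpec("x", "benthic", 10, 0.5)
        with pytest.raises(ValueError):
            PopulationSpec("x", "shore", 0, 0.5)
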