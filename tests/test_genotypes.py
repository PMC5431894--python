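"""Allele frequencies, Mendelian assignment, FST (vs brute force) and LD."""

import numpy as np
import pandas as pd
import pytest

from conftest import FIVE_SYSTEMS, miscall_table
from nerkasweep.genotypes import (
    FreqSummary,
    assignment_accuracy,
    fst_pair,
    full_linkage,
    ld_r2,
    mendelian_assign,
    summarize_frequencies,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "ecotype", "genotype"]
    )


def _pop(pop, ecotype, genotypes):
    return [
        {"sample_id": f"{pop}_{i}", "population": pop, "ecotype": ecotype, "genotype": g}
        for i, g in enumerate(genotypes)
    ]


class TestFrequencies:
    def test_all_gg_gives_p_one(self):
        out = summarize_frequencies(_table(_pop("x", "shore", ["GG"] * 10)))
        assert out[0].p_g == 1.0 and out[0].n == 10

    def test_okanagan_counts(self):
        genos = ["GG"] * 141 + ["GT"] * 3
        out = summarize_frequencies(_table(_pop("ok", "shore", genos)))
        assert out[0].p_g == pytest.approx(285 / 288)
        assert round(out[0].p_g, 2) == 0.99

    def test_symmetric_counts_give_half(self):
        out = summarize_frequencies(_table(_pop("x", "shore", ["GG", "GT", "GT", "TT"])))
        assert out[0].p_g == 0.5

    def test_missing_excluded_and_allele_frequencies_sum_to_one(self):
        out = summarize_frequencies(_table(_pop("x", "shore", ["GG", "NN", "GT", "NN"])))
        assert out[0].n == 2
        assert out[0].p_g + out[0].p_t == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_population_excluded(self):
        rows = _pop("empty", "shore", ["NN", "NN"]) + _pop("ok", "shore", ["GG"])
        out = summarize_frequencies(_table(rows))
        assert [f.population for f in out] == ["ok"]

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="AG"):
            summarize_frequencies(_table(_pop("x", "shore", ["AG"])))


class TestMendelianRule:
    @pytest.mark.parametrize(
        "genotype,expected",
        [("GG", "shore"), ("GT", "stream"), ("TT", "stream"), ("NN", "unassigned")],
    )
    def test_rule(self, genotype, expected):
        assert mendelian_assign(genotype) == expected

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="'GA'"):
            mendelian_assign("GA")


class TestAssignmentAccuracy:
    def test_five_system_miscall_fixture(self):
        report = assignment_accuracy(miscall_table(), FIVE_SYSTEMS)
        assert report.correct == 569
        assert report.incorrect == 5
        assert report.accuracy_pct == pytest.approx(100 * 569 / 574)
        assert report.accuracy_pct > 99.0
        assert report.gg_in_stream == 1
        assert report.gt_in_shore == 4
        assert report.tt_in_shore == 0
        assert report.n_stream == 238 and report.n_shore == 336

    def test_fully_concordant_table(self):
        rows = _pop("a", "shore", ["GG"] * 5) + _pop("b", "stream", ["GT", "TT", "TT"])
        report = assignment_accuracy(_table(rows), ["a", "b"])
        assert report.accuracy_pct == 100.0

    def test_stream_population_entirely_gg_contributes_zero_correct(self):
        rows = _pop("odd", "stream", ["GG"] * 4) + _pop("a", "shore", ["GG"])
        report = assignment_accuracy(_table(rows), ["odd", "a"])
        per = report.per_population.set_index("population")
        assert per.loc["odd", "correct"] == 0
        assert per.loc["odd", "incorrect"] == 4

    def test_unassigned_excluded_from_denominator(self):
        rows = _pop("a", "shore", ["GG", "NN", "NN"])
        report = assignment_accuracy(_table(rows), ["a"])
        assert report.correct + report.incorrect == 1

    def test_empty_system_list_rejected(self):
        with pytest.raises(ValueError):
            assignment_accuracy(miscall_table(), [])

    def test_missing_population_rejected(self):
        with pytest.raises(ValueError, match="Nowhere Lake"):
            assignment_accuracy(miscall_table(), ["Nowhere Lake"])


def _freq(pop, n_gg, n_gt, n_tt):
    return FreqSummary(pop, n_gg + n_gt + n_tt, n_gg, n_gt, n_tt)


class TestFst:
    def test_equal_frequencies_give_zero(self):
        a = _freq("a", 25, 50, 25)
        b = _freq("b", 25, 50, 25)
        assert fst_pair(a, b, "nei_gst").value == pytest.approx(0.0, abs=1e-12)
        assert fst_pair(a, b, "weir_cockerham").value <= 0.0  # unbiased: <= 0 here

    def test_opposite_fixation_gives_one(self):
        res = fst_pair(_freq("a", 10, 0, 0), _freq("b", 0, 0, 10), "nei_gst")
        assert res.value == pytest.approx(1.0)

    def test_hand_computed_gst_example(self):
        # p_A = 0.99, p_B = 0.10: H_S = (2*.99*.01 + 2*.1*.9)/2, H_T = 2*.545*.455
        a = FreqSummary("a", 100, 99, 0, 1)  # p = 0.99
        b = FreqSummary("b", 100, 10, 0, 90)  # p = 0.10
        res = fst_pair(a, b, "nei_gst")
        expected = 1.0 - ((2 * 0.99 * 0.01 + 2 * 0.10 * 0.90) / 2) / (2 * 0.545 * 0.455)
        assert res.value == pytest.approx(expected, abs=1e-12)
        assert res.value == pytest.approx(0.799, abs=5e-4)

    def test_same_allele_fixed_in_both_is_undefined(self):
        res = fst_pair(_freq("a", 5, 0, 0), _freq("b", 8, 0, 0), "nei_gst")
        assert res.undefined and np.isnan(res.value)

    def test_label_swap_invariance(self, rng):
        a = _freq("a", 12, 30, 8)
        b = _freq("b", 40, 5, 2)
        for est in ("nei_gst", "weir_cockerham"):
            assert fst_pair(a, b, est).value == pytest.approx(fst_pair(b, a, est).value, abs=1e-12)

    def test_gst_monotone_in_frequency_difference(self):
        # mirrored pairs (p, 1-p) hold within-population heterozygosity equal
        values = []
        for p in (0.45, 0.35, 0.25, 0.15, 0.05):
            a = FreqSummary("a", 50, int(100 * p * p), 0, 0)
            # build exact frequencies via allele counts: use n=50, 2n=100 alleles
            n_g = int(round(100 * p))
            a = FreqSummary("a", 50, n_g // 2, n_g % 2, 50 - n_g // 2 - n_g % 2)
            n_g2 = 100 - n_g
            b = FreqSummary("b", 50, n_g2 // 2, n_g2 % 2, 50 - n_g2 // 2 - n_g2 % 2)
            values.append(fst_pair(a, b, "nei_gst").value)
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_estimators_match_brute_force_on_random_tables(self, rng):
        """Both estimators vs independently coded formulas, 100 random tables."""
        for _ in range(100):
            counts = rng.integers(0, 30, size=6)
            counts[0] += 1
            counts[3] += 1
            fa = _freq("a", counts[0], counts[1], counts[2])
            fb = _freq("b", counts[3], counts[4], counts[5])

            # brute-force Nei GST from explicit heterozygosities
            pa, pb = fa.p_g, fb.p_g
            hs = ((2 * pa * (1 - pa)) + (2 * pb * (1 - pb))) / 2
            pbar = (pa + pb) / 2
            ht = 1 - pbar**2 - (1 - pbar) ** 2
            res = fst_pair(fa, fb, "nei_gst")
            if ht == 0:
                assert res.undefined
            else:
                assert res.value == pytest.approx(1 - hs / ht, abs=1e-9)

            # brute-force Weir-Cockerham from per-individual allele indicators
            wc = fst_pair(fa, fb, "weir_cockerham")
            a_comp, b_comp, c_comp = _wc_brute_force(fa, fb)
            assert wc.components["a"] == pytest.approx(a_comp, abs=1e-9)
            assert wc.components["b"] == pytest.approx(b_comp, abs=1e-9)
            assert wc.components["c"] == pytest.approx(c_comp, abs=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            fst_pair(FreqSummary("a", 0, 0, 0, 0), _freq("b", 1, 0, 0))


def _wc_brute_force(fa, fb):
    """Weir & Cockerham (1984) single-locus components, coded from the
    published sums rather than the package's vectorized path."""
    r = 2
    data = [(fa.n, fa.p_g, fa.n_gt / fa.n), (fb.n, fb.p_g, fb.n_gt / fb.n)]
    nbar = sum(n for n, _, _ in data) / r
    nc = (r * nbar - sum(n * n for n, _, _ in data) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in data) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in data) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in data) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestLinkageDisequilibrium:
    def test_perfect_coupling_gives_r2_one(self):
        haps = ["AG"] * 4 + ["TC"] * 4
        out = ld_r2(haps)
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert full_linkage(out)

    def test_independent_assortment_gives_zero(self):
        out = ld_r2(["AG", "AC", "TG", "TC"])
        assert out["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_intermediate_example(self):
        # haplotype counts AB=3, Ab=1, aB=1, ab=3 -> D=0.125, r2=0.25
        haps = ["AG"] * 3 + ["AC"] + ["TG"] + ["TC"] * 3
        out = ld_r2(haps)
        assert out["r2"].iloc[0] == pytest.approx(0.25)

    def test_monomorphic_site_flagged(self):
        out = ld_r2(["AG", "AG", "AC", "AC"])
        assert not out["defined"].iloc[0]
        assert np.isnan(out["r2"].iloc[0])

    def test_three_sites_all_pairs(self):
        out = ld_r2(["AGT"] * 5 + ["TCA"] * 3)
        assert len(out) == 3
        assert full_linkage(out)
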