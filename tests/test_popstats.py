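import math

import numpy as np
import pandas as pd
import pytest

from introkasp import (
    allele_frequencies,
    bh_adjust,
    exact_test_rxc,
    fisher_exact_2x2,
    sign_test,
    temporal_exact_tests,
    wilcoxon_signed_rank_one_sided,
)
from conftest import make_matrix
from oracles import (
    enumerate_fisher_2x2,
    enumerate_freeman_halton,
    enumerate_sign_test_two_sided,
    enumerate_wilcoxon_less,
)


class TestAlleleFrequencies:
    def test_dosage_counting(self, tiny_matrix, panel):
        freqs = allele_frequencies(tiny_matrix, panel, markers=["SNP15"])
        rec = freqs.iloc[0]
        assert rec["robusta_freq"] == pytest.approx(3 / 8)
        assert rec["n_called_alleles"] == 8

    def test_all_missing_undefined(self, panel):
        gm = make_matrix({"SNP15": [None, None]})
        freqs = allele_frequencies(gm, panel, markers=["SNP15"])
        assert freqs.iloc[0]["n_called_alleles"] == 0
        assert np.isnan(freqs.iloc[0]["robusta_freq"])

    def test_missing_excluded_from_denominator(self, panel):
        gm = make_matrix({"SNP15": [2, None, 0]})
        freqs = allele_frequencies(gm, panel, markers=["SNP15"])
        assert freqs.iloc[0]["robusta_freq"] == pytest.approx(0.5)

    def test_estimate_within_binomial_interval(self, panel):
        # sampling oracle: dosages ~ Binomial(2, 0.30), n = 500 individuals;
        # the estimate must fall inside the binomial 99% interval
        rng = np.random.default_rng(11)
        p, n = 0.30, 500
        gm = make_matrix({"SNP15": rng.binomial(2, p, size=n).astype(float)})
        freqs = allele_frequencies(gm, panel, markers=["SNP15"])
        half = 2.576 * math.sqrt(p * (1 - p) / (2 * n))
        assert abs(freqs.iloc[0]["robusta_freq"] - p) < half


class TestFisher2x2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[3, 7], [3, 7]], 1.0),
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(table).p_value == pytest.approx(expected)

    def test_zero_margin_degenerate(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0 and res.degenerate

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            got = fisher_exact_2x2(table).p_value
            want = enumerate_fisher_2x2(table)
            assert math.isclose(got, want, rel_tol=1e-9), table


class TestFreemanHalton:
    def test_identical_rows(self):
        res = exact_test_rxc([[3, 7, 2], [3, 7, 2]])
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_subcase_equals_fisher(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            table = rng.integers(0, 10, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            assert math.isclose(
                exact_test_rxc(table).p_value,
                fisher_exact_2x2(table).p_value,
                rel_tol=1e-9,
            )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            table = rng.integers(0, 8, size=(2, 3))
            got = exact_test_rxc(table).p_value
            want = enumerate_freeman_halton(table)
            assert math.isclose(got, want, rel_tol=1e-9), table

    def test_monte_carlo_fallback_needs_rng(self):
        big = np.full((2, 3), 500)
        with pytest.raises(ValueError, match="rng"):
            exact_test_rxc(big, max_tables=100)
        res = exact_test_rxc(big, max_tables=100,
                             rng=np.random.default_rng(0), n_monte_carlo=2000)
        assert res.p_value == pytest.approx(1.0, abs=0.05)


class TestBhAdjust:
    def test_closed_form(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestWilcoxon:
    def test_all_decreases_extreme(self):
        before = [0.30, 0.25, 0.40, 0.35, 0.20]
        after = [0.20, 0.17, 0.34, 0.31, 0.18]  # five distinct decreases
        res = wilcoxon_signed_rank_one_sided(before, after, alternative="less")
        assert res.p_value == pytest.approx(1 / 32)

    def test_mirrored_differences_not_significant(self):
        before = np.zeros(8)
        after = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4])
        res = wilcoxon_signed_rank_one_sided(before, after, alternative="less")
        assert res.p_value > 0.3

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank_one_sided([1, 2], [1, 2])
        assert res.p_value == 1.0 and res.degenerate
        assert res.extras["n_zeros"] == 2

    def test_zeros_discarded_and_counted(self):
        res = wilcoxon_signed_rank_one_sided(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1.0, 1.5, 2.7, 3.9, 4.2, 5.1],
        )
        assert res.extras["n_zeros"] == 1
        assert res.extras["n_used"] == 5

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = rng.integers(4, 11)
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank_one_sided(np.zeros(n), d, alternative="less")
            assert res.extras["method"] == "exact"
            assert math.isclose(res.p_value, enumerate_wilcoxon_less(d),
                                rel_tol=1e-12)


class TestSignTest:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(8, 9, 20 / 512), (9, 10, 22 / 1024), (5, 10, 1.0)],
    )
    def test_known_values(self, k, n, expected):
        assert sign_test(k, n).p_value == pytest.approx(expected)

    def test_matches_enumeration(self):
        for n in range(1, 13):
            for k in range(n + 1):
                assert math.isclose(
                    sign_test(k, n).p_value,
                    enumerate_sign_test_two_sided(k, n),
                    rel_tol=1e-12,
                )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sign_test(1, 0)
        with pytest.raises(ValueError):
            sign_test(5, 3)


class TestTemporalTests:
    def test_identical_counts_give_p_one(self, panel):
        gm = make_matrix(
            {"SNP15": [2, 1, 0, 2, 1, 0]},
            populations=["popA"] * 6,
            periods=["P2012"] * 3 + ["P2021"] * 3,
        )
        results = temporal_exact_tests(gm, panel, scope="per_population")
        assert len(results) == 2  # allelic + genotypic
        for r in results:
            assert r.p_value == pytest.approx(1.0)

    def test_population_missing_a_period_skipped(self, panel):
        gm = make_matrix(
            {"SNP15": [2, 1, 0]},
            populations=["popA", "popA", "popB"],
            periods=["P2012", "P2021", "P2012"],
        )
        results = temporal_exact_tests(gm, panel, scope="per_population")
        labels = {r.label for r in results}
        assert all("popA" in lab for lab in labels)

    def test_rare_allele_loss_not_significant_after_adjustment(self, panel):
        # one rare-allele population (1 copy in 15 individuals in the first
        # period, absent in the second) among unchanged populations: its
        # BH-adjusted p must stay clearly non-significant
        dosages, pops, periods = [], [], []
        dosages += [1] + [0] * 14 + [0] * 15
        pops += ["stvaast"] * 30
        periods += ["P2012"] * 15 + ["P2021"] * 15
        for i in range(4):
            dosages += [1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0]
            pops += [f"pop{i}"] * 12
            periods += ["P2012"] * 6 + ["P2021"] * 6
        gm = make_matrix({"SNP15": dosages}, populations=pops, periods=periods)
        results = temporal_exact_tests(gm, panel, scope="per_population")
        sv = [r for r in results if r.label.startswith("stvaast")]
        assert sv and all(r.p_adjusted > 0.2 for r in sv)

    def test_pooled_scope_covers_island_markers(self, panel):
        rng = np.random.default_rng(10)
        markers = panel.island_marker_ids
        n = 40
        gm = make_matrix(
            {m: rng.binomial(2, 0.3, size=n).astype(float) for m in markers},
            periods=["P2012"] * (n // 2) + ["P2021"] * (n // 2),
        )
        results = temporal_exact_tests(gm, panel, scope="pooled")
        assert len(results) == 2 * len(markers)

    def test_null_type_one_error_calibrated(self, panel):
        # no true temporal change: allelic counts drawn from the same
        # binomial in both periods; empirical rejection at 0.05 must sit
        # near nominal (exact tests are mildly conservative)
        rng = np.random.default_rng(12)
        n_alleles, p = 600, 0.3
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.binomial(n_alleles, p)
            b = rng.binomial(n_alleles, p)
            tab = [[a, n_alleles - a], [b, n_alleles - b]]
            if fisher_exact_2x2(tab).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_bh_adjusted_null_rejections_bounded(self, panel):
        # 14 populations, 1,000 replicates of no-change null: the fraction
        # of BH-adjusted p-values below 0.05 stays below ~7%
        rng = np.random.default_rng(13)
        n_alleles, p = 80, 0.3
        n_sig = 0
        total = 0
        for _ in range(1000):
            ps = []
            for _ in range(14):
                a = rng.binomial(n_alleles, p)
                b = rng.binomial(n_alleles, p)
                ps.append(
                    fisher_exact_2x2(
                        [[a, n_alleles - a], [b, n_alleles - b]]
                    ).p_value
                )
            adj = bh_adjust(ps)
            n_sig += int((adj < 0.05).sum())
            total += 14
        assert n_sig / total <= 0.07

    def test_power_against_real_decline(self, panel):
        # pooled shoulder-erosion alternative: frequency 0.15 -> 0.05
        # (decline 0.10) with ~450 individuals per period must be detected
        # with power > 80%
        rng = np.random.default_rng(14)
        n_alleles = 900
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.binomial(n_alleles, 0.15)
            b = rng.binomial(n_alleles, 0.05)
            tab = [[a, n_alleles - a], [b, n_alleles - b]]
            if fisher_exact_2x2(tab).p_value < 0.05:
                hits += 1
        assert hits / reps > 0.8
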