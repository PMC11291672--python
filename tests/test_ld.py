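import numpy as np
import pandas as pd
import pytest

from introkasp import (
    em_haplotype_freqs,
    ld_from_dosages,
    ld_matrices,
    ld_temporal_compare,
    mean_r2,
    two_locus_counts,
)
from conftest import make_matrix
from oracles import grid_search_loglik


def random_dosage_table(rng, n_max=60):
    """Random 3×3 dosage table drawn from a random haplotype model."""
    p = rng.dirichlet(np.ones(4))
    n = rng.integers(10, n_max)
    haps = rng.choice(4, size=(n, 2), p=p)
    a = (haps < 2).sum(axis=1)          # haplotypes 0,1 carry allele A
    b = ((haps == 0) | (haps == 2)).sum(axis=1)  # haplotypes 0,2 carry B
    return two_locus_counts(a, b)


class TestEmEstimator:
    def test_perfect_association(self):
        a = [2] * 50 + [0] * 50
        est = ld_from_dosages(a, a)
        assert est.r2 == pytest.approx(1.0)
        assert est.D == pytest.approx(0.25)
        assert est.hap_freqs[0] == pytest.approx(0.5)
        assert est.hap_freqs[3] == pytest.approx(0.5)

    def test_no_double_heterozygotes_equals_direct_counting(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(40):
            counts = random_dosage_table(rng)
            if counts[1, 1] != 0:
                counts[1, 1] = 0
            if counts.sum() == 0:
                continue
            est = em_haplotype_freqs(counts)
            n = counts.sum()
            direct = np.array([
                2 * counts[2, 2] + counts[2, 1] + counts[1, 2],
                2 * counts[2, 0] + counts[2, 1] + counts[1, 0],
                2 * counts[0, 2] + counts[1, 2] + counts[0, 1],
                2 * counts[0, 0] + counts[1, 0] + counts[0, 1],
            ]) / (2 * n)
            assert est.hap_freqs == pytest.approx(direct, abs=1e-12)
            checked += 1
        assert checked >= 30

    def test_single_double_heterozygote_stays_at_equilibrium(self):
        # the two phase resolutions are symmetric: EM must stay at D = 0
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 1
        est = em_haplotype_freqs(counts)
        assert est.D == pytest.approx(0.0, abs=1e-12)
        assert est.r2 == pytest.approx(0.0, abs=1e-12)

    def test_loglik_beats_grid_search(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            counts = random_dosage_table(rng)
            if counts.sum() == 0:
                continue
            est = em_haplotype_freqs(counts)
            assert est.converged
            assert est.loglik >= grid_search_loglik(counts) - 1e-6

    def test_loglik_monotone(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            counts = random_dosage_table(rng)
            if counts.sum() == 0:
                continue
            em_haplotype_freqs(counts, check_monotone=True)  # asserts inside

    def test_monomorphic_r2_undefined(self):
        est = ld_from_dosages([2, 2, 2, 2], [0, 1, 2, 1])
        assert np.isnan(est.r2)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            em_haplotype_freqs(np.zeros((3, 3)))


class TestR2Invariants:
    def test_symmetry_under_allele_swap_and_locus_exchange(self):
        rng = np.random.default_rng(24)
        for _ in range(25):
            counts = random_dosage_table(rng)
            if counts.sum() < 4:
                continue
            base = em_haplotype_freqs(counts).r2
            swapped_a = em_haplotype_freqs(counts[::-1, :].copy()).r2
            swapped_b = em_haplotype_freqs(counts[:, ::-1].copy()).r2
            exchanged = em_haplotype_freqs(counts.T.copy()).r2
            for other in (swapped_a, swapped_b, exchanged):
                if np.isnan(base):
                    assert np.isnan(other)
                else:
                    assert other == pytest.approx(base, abs=1e-9)

    def test_r2_range(self):
        rng = np.random.default_rng(25)
        for _ in range(50):
            counts = random_dosage_table(rng)
            if counts.sum() == 0:
                continue
            r2 = em_haplotype_freqs(counts).r2
            if not np.isnan(r2):
                assert -1e-12 <= r2 <= 1 + 1e-12

    def test_r2_one_iff_two_complementary_haplotypes(self):
        a = [2] * 30 + [0] * 20 + [1] * 10
        est = ld_from_dosages(a, a)
        assert est.r2 == pytest.approx(1.0)
        # break the perfect association with one recombinant genotype
        b = list(a)
        b[0] = 0
        assert ld_from_dosages(a, b).r2 < 1.0

    def test_phase_known_simulation_rmse(self):
        # EM from unphased genotypes vs truth from the generating haplotype
        # frequencies: RMSE < 0.02 at n = 200 and shrinking with n
        rng = np.random.default_rng(26)

        def rmse(n, reps=40):
            errs = []
            while len(errs) < reps:
                p = rng.dirichlet([4, 2, 2, 4])
                pA, pB = p[0] + p[1], p[0] + p[2]
                denom = pA * (1 - pA) * pB * (1 - pB)
                if denom < 0.01:
                    continue
                true_r2 = (p[0] - pA * pB) ** 2 / denom
                haps = rng.choice(4, size=(n, 2), p=p)
                a = (haps < 2).sum(axis=1)
                b = ((haps == 0) | (haps == 2)).sum(axis=1)
                est = ld_from_dosages(a, b)
                if np.isnan(est.r2):
                    continue
                errs.append((est.r2 - true_r2) ** 2)
            return np.sqrt(np.mean(errs))

        r200 = rmse(200)
        r800 = rmse(800)
        assert r200 < 0.05
        assert r800 < 0.8 * r200  # roughly halves when n quadruples


def ld_matrix_input(core_freq, panel, n=50, seed=0, periods=("P2012",)):
    rng = np.random.default_rng(seed)
    markers = panel.island_marker_ids
    data = {}
    for m in markers:
        p = core_freq if m == panel.core_marker_id else 0.3
        data[m] = rng.binomial(2, p, size=n * len(periods)).astype(float)
    return make_matrix(
        data, periods=[p for p in periods for _ in range(n)]
    )


class TestLdMatrices:
    def test_low_core_frequency_population_excluded(self, panel):
        gm = ld_matrix_input(0.02, panel, seed=31)
        ldl = ld_matrices(gm, panel, min_core_freq=0.05)
        assert not ldl["included"].any()

    def test_core_frequency_above_threshold_included(self, panel):
        gm = ld_matrix_input(0.30, panel, seed=32)
        ldl = ld_matrices(gm, panel, min_core_freq=0.05)
        assert ldl["included"].all()
        assert len(ldl) == 45

    def test_mean_r2_simple_and_union(self, panel):
        ldl = pd.DataFrame(
            {
                "population_id": ["a"] * 3 + ["b"] * 2,
                "period": ["P2012"] * 5,
                "marker_a": ["m1", "m1", "m2", "m3", "m4"],
                "marker_b": ["m2", "m3", "m3", "m4", "m5"],
                "r2": [0.2, 0.1, 0.3, 0.5, np.nan],
                "included": [True] * 5,
            }
        )
        assert mean_r2(ldl.iloc[:3], "P2012") == pytest.approx(0.2)
        # two populations with disjoint defined pairs: mean over the union
        assert mean_r2(ldl, "P2012") == pytest.approx((0.2 + 0.1 + 0.3 + 0.5) / 4)


class TestTemporalCompare:
    def build_long(self, r2_by_period, panel):
        rows = []
        for period, factor in r2_by_period.items():
            for a, b, cls in panel.island_pairs():
                rows.append(
                    {
                        "population_id": "p1", "period": period,
                        "marker_a": a, "marker_b": b,
                        "pair_class": cls.value, "r2": 0.4 * factor,
                        "included": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_uniform_decrease_counts(self, panel):
        ldl = self.build_long({"P2012": 1.0, "P2021": 0.5}, panel)
        delta, tests = ld_temporal_compare(ldl, panel)
        assert (delta["delta"] < 0).all()
        by_label = {t.label: t for t in tests}
        assert by_label["core_shoulder:sign"].extras["n_decreases"] == 9
        assert by_label["left_shoulder:sign"].extras["n_decreases"] == 6
        assert by_label["right_shoulder:sign"].extras["n_decreases"] == 10
        assert by_label["all_pairs:sign"].extras["n_decreases"] == 45

    def test_identical_periods_degenerate(self, panel):
        ldl = self.build_long({"P2012": 1.0, "P2021": 1.0}, panel)
        delta, tests = ld_temporal_compare(ldl, panel)
        assert (delta["delta"] == 0).all()
        for t in tests:
            if t.test_name == "wilcoxon_signed_rank":
                assert t.degenerate and t.p_value == 1.0

    def test_pair_missing_in_one_period_excluded(self, panel):
        ldl = self.build_long({"P2012": 1.0, "P2021": 0.5}, panel)
        drop = (ldl["period"] == "P2021") & (ldl["marker_a"] == "SNP15")
        delta, _ = ld_temporal_compare(ldl[~drop], panel)
        assert len(delta) == 45 - (ldl[drop]["marker_b"].nunique())
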