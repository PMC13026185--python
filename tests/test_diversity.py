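import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scatgen.diversity import (
    bh_fdr,
    column_summary,
    diversity_table,
    friedman_locality_comparison,
    hwe_exact_test,
    ld_pairwise_test,
)
from tests.conftest import random_genotypes

TABLE1 = {
    "na": [3, 2, 3, 4, 5, 2, 3, 4],
    "ar": [3.00, 2.00, 3.94, 3.94, 4.94, 2.94, 3.00, 4.00],
    "ho": [0.63, 0.38, 0.63, 0.75, 0.88, 0.50, 0.88, 0.86],
    "he": [0.57, 0.43, 0.53, 0.67, 0.75, 0.50, 0.57, 0.64],
}


class TestColumnSummary:
    def test_na_mean_and_se(self):
        mean, se = column_summary(TABLE1["na"])
        assert round(mean, 2) == 3.25 and round(se, 2) == 0.37

    def test_ar_mean(self):
        assert round(column_summary(TABLE1["ar"])[0], 2) == 3.47

    def test_overall_row_reproduction(self):
        assert round(column_summary(TABLE1["ho"])[0], 2) == 0.69
        assert round(column_summary(TABLE1["he"])[0], 2) == 0.58


class TestDiversityTable:
    def test_all_het_biallelic(self):
        genos = {f"i{k}": {"L": (1, 2)} for k in range(10)}
        t = diversity_table(genos)
        row = t.rows[0]
        assert row.ho == 1.0 and row.he == pytest.approx(0.5)

    def test_ar_equals_na_at_full_depth(self):
        rng = np.random.default_rng(0)
        genos = random_genotypes(rng, 12, 4)
        t = diversity_table(genos)
        for row in t.rows:
            # equal gene counts across loci => rarefaction depth = full count
            assert row.ar == pytest.approx(row.na)
            assert 1 <= row.ar <= row.na + 1e-9

    def test_he_invariant_to_relabeling(self):
        genos = {f"i{k}": {"L": (1, 2) if k % 2 else (2, 2)} for k in range(8)}
        relab = {f"i{k}": {"L": (11, 12) if k % 2 else (12, 12)} for k in range(8)}
        assert diversity_table(genos).rows[0].he == \
            pytest.approx(diversity_table(relab).rows[0].he)

    def test_all_missing_locus_excluded(self):
        genos = {"a": {"L": (1, 2), "M": None}, "b": {"L": (1, 1), "M": None}}
        t = diversity_table(genos)
        assert t.excluded_loci == ["M"]

    def test_fis_all_het_negative(self):
        genos = {f"i{k}": {"L": (1, 2)} for k in range(20)}
        assert diversity_table(genos).rows[0].fis < -0.9


class TestHwe:
    def test_perfect_hw_large_n_p_near_one(self):
        genos = {}
        i = 0
        for g, n in (((1, 1), 25), ((1, 2), 50), ((2, 2), 25)):
            for _ in range(n):
                genos[f"i{i}"] = {"L": g}
                i += 1
        p = hwe_exact_test(genos, "L", n_perm=499, seed=1)
        assert p > 0.5

    def test_all_homozygotes_rejected(self):
        genos = {f"i{k}": {"L": (1, 1) if k < 10 else (2, 2)} for k in range(20)}
        assert hwe_exact_test(genos, "L", n_perm=999, seed=1) < 0.01

    def test_monomorphic_returns_one(self):
        genos = {f"i{k}": {"L": (1, 1)} for k in range(10)}
        assert hwe_exact_test(genos, "L", n_perm=99, seed=0) == 1.0

    def test_zero_permutations_rejected(self):
        genos = {f"i{k}": {"L": (1, 2)} for k in range(10)}
        with pytest.raises(ValueError):
            hwe_exact_test(genos, "L", n_perm=0, seed=0)

    def test_null_calibration(self):
        # Monte Carlo p is discrete and mildly conservative (+1/+1), so
        # check rejection-rate bands rather than strict KS uniformity.
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(150):
            genos = random_genotypes(rng, 20, 1, k=3)
            ps.append(hwe_exact_test(genos, "L0", n_perm=199, seed=rep))
        ps = np.asarray(ps)
        assert np.mean(ps <= 0.05) <= 0.10
        assert 0.05 <= np.mean(ps <= 0.25) <= 0.40


class TestLd:
    def test_duplicated_locus_minimal_p(self):
        rng = np.random.default_rng(0)
        genos = {}
        for k in range(30):
            a, b = sorted(rng.integers(1, 4, 2))
            genos[f"i{k}"] = {"A": (int(a), int(b)), "B": (int(a), int(b))}
        p = ld_pairwise_test(genos, n_perm=199, seed=2)[("A", "B")]
        assert p <= 2 / 200

    def test_single_polymorphic_locus_empty(self):
        genos = {f"i{k}": {"A": (1, 2), "B": (5, 5)} for k in range(10)}
        assert ld_pairwise_test(genos, n_perm=99, seed=0) == {}

    def test_sparse_pair_flagged_missing(self):
        genos = {f"i{k}": {"A": (1, 2) if k < 4 else None,
                           "B": (3, 4) if k < 4 else (3, 3)} for k in range(10)}
        res = ld_pairwise_test(genos, n_perm=99, seed=0)
        assert res[("A", "B")] is None

    def test_null_calibration(self):
        # sample large enough that the permutation p is effectively
        # continuous; at very small n the discrete null is conservative
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(200):
            genos = random_genotypes(rng, 30, 2, k=3)
            p = ld_pairwise_test(genos, n_perm=99, seed=rep)[("L0", "L1")]
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_unchanged(self):
        assert bh_fdr([0.123]) == [0.123]

    def test_stepup_hand_case(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(25)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw(self, p):
        adj = bh_fdr(p)
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))
        assert all(0 <= a <= 1 for a in adj)


class TestFriedman:
    def test_identical_columns(self):
        res = friedman_locality_comparison(np.ones((4, 3)))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_df_matches_locality_count(self):
        rng = np.random.default_rng(1)
        mat = rng.random((4, 9))
        res = friedman_locality_comparison(mat)
        assert res.df == 8 and res.method == "asymptotic"
        # statistic agrees with scipy for the untied case
        chi2_scipy = stats.friedmanchisquare(*(mat[:, j] for j in range(9)))[0]
        assert res.chi2 == pytest.approx(chi2_scipy)

    def test_exact_binomial_two_columns(self):
        mat = np.array([[1.0, 2.0]] * 4)
        res = friedman_locality_comparison(mat)
        assert res.method == "exact"
        assert res.p == pytest.approx(0.125)

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing cells"):
            friedman_locality_comparison(mat)

    def test_pairwise_emitted_when_significant(self):
        rng = np.random.default_rng(3)
        base = rng.random(8)
        mat = np.column_stack([base, base + 1.0, base + 2.0])
        res = friedman_locality_comparison(mat)
        assert res.p < 0.05 and res.pairwise is not None
        assert len(res.pairwise) == 3
        for row in res.pairwise:
            assert row["p_adj"] >= row["p_raw"] - 1e-12
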