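import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from faecomir.quantify import CountMatrix
from faecomir.variability import (
    cv_ranking,
    detection_summary,
    robust_cv,
    size_factors,
    spearman,
    stability_report,
    wilcoxon_signed_rank,
)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [3, 7, 2], "b": [3, 7, 2], "c": [3, 7, 2]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_doubles_factor(self):
        df = pd.DataFrame({"a": [4, 10, 6], "b": [8, 20, 12]})
        sf = size_factors(df)
        assert math.isclose(sf["b"] / sf["a"], 2.0)

    def test_hand_computed_three_by_three(self):
        df = pd.DataFrame([[2, 4, 8], [1, 2, 4], [4, 8, 16]],
                          columns=["a", "b", "c"])
        sf = size_factors(df)
        assert np.allclose(sf.to_numpy(), [0.5, 1.0, 2.0])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(20, size=(30, 4)) + 1,
                          columns=list("abcd"))
        base = size_factors(df)
        scaled = df.copy()
        scaled["c"] = scaled["c"] * 3
        sf = size_factors(scaled)
        assert math.isclose((sf["c"] / sf["a"]) / (base["c"] / base["a"]), 3.0,
                            rel_tol=1e-9)

    def test_sparse_fallback_warns(self, caplog):
        df = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with caplog.at_level("WARNING", logger="faecomir"):
            sf = size_factors(df)
        assert "positive-subset" in caplog.text
        assert (sf > 0).all()


class TestDetection:
    def test_all_zero_matrix(self):
        df = pd.DataFrame(0, index=["m1", "m2"], columns=["s1", "s2"])
        det = detection_summary(df)
        assert (det.prevalence == 0).all()

    def test_half_prevalence_counts_in_at_least_half_set(self):
        df = pd.DataFrame([[1, 2, 5, 0, 0, 0]], index=["m"],
                          columns=list("abcdef"))
        det = detection_summary(df)
        assert det.prevalence["m"] == 0.5
        assert det.detected_at_least_half == 1

    def test_prevalence_monotone_in_min_reads(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.poisson(2, size=(50, 8)))
        prev = [detection_summary(df, min_reads=k).prevalence.sum()
                for k in (1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(prev, prev[1:]))

    def test_fully_detected_chromosome_fraction_is_one(self):
        df = pd.DataFrame([[3, 1], [0, 0], [2, 2]],
                          index=["a-5p", "a-3p", "b-5p"], columns=["s1", "s2"])
        chrom = pd.Series({"a-5p": "chr1", "a-3p": "chr1", "b-5p": "chrY"})
        det = detection_summary(df, chromosome=chrom)
        assert det.chromosome_fraction["chrY"] == 1.0
        assert det.chromosome_fraction["chr1"] == 0.5


class TestRobustCV:
    def test_hand_computed_example(self):
        rec = robust_cv([2, 4, 4, 4, 5, 5, 7, 9])
        assert rec.median_expr == 4.5 and rec.mad == 0.5
        assert math.isclose(rec.cv, 0.1111, abs_tol=5e-5)

    def test_constant_row_zero_cv(self):
        rec = robust_cv([5, 5, 5, 5])
        assert rec.mad == 0 and rec.cv == 0

    @given(st.floats(0.1, 1000), st.integers(0, 5))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        row = rng.uniform(1, 50, size=12)
        assert math.isclose(robust_cv(row).cv, robust_cv(row * scale).cv,
                            rel_tol=1e-9)

    def test_low_median_rejected(self):
        with pytest.raises(ValueError):
            robust_cv([0.1, 0.2, 0.3])

    def test_ranking_filters_and_orders(self):
        df = pd.DataFrame({
            "s1": [10, 0.2, 5], "s2": [12, 0.3, 5], "s3": [30, 0.1, 5],
            "s4": [11, 0.2, 5]},
            index=["variable", "too_low", "stable"])
        ranked = cv_ranking(df)
        assert list(ranked["mirna"]) == ["stable", "variable"]
        assert "too_low" not in set(ranked["mirna"])
        assert list(ranked["rank"]) == [1, 2]

    def test_mean_mad_switch(self):
        rec = robust_cv([2, 4, 4, 4, 5, 5, 7, 9], mad_kind="mean")
        dev = np.abs(np.array([2, 4, 4, 4, 5, 5, 7, 9]) - 4.5)
        assert math.isclose(rec.mad, dev.mean())


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(1, 11, dtype=float)
        rho, _ = spearman(x, x ** 2)
        assert math.isclose(rho, 1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(1, 11, dtype=float)
        rho, _ = spearman(x, -x)
        assert math.isclose(rho, -1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        rho, _ = spearman(x, y)
        oracle = sps.spearmanr(x, y).statistic
        assert math.isclose(rho, oracle, rel_tol=1e-12)

    def test_exact_permutation_p_small_n(self):
        # perfectly concordant n=4: 2 of 4! orderings reach |rho| = 1
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and math.isclose(p, 2 / 24)

    def test_zero_variance_flagged(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        p = wilcoxon_signed_rank([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6])
        assert math.isclose(p, 2 / 64)

    def test_identical_vectors_give_one(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_matches_brute_force_enumeration_up_to_n8(self):
        rng = np.random.default_rng(3)
        for n in range(2, 9):
            for _ in range(5):
                d = rng.integers(-9, 10, size=n).astype(float)
                d[d == 0] = 1.0
                a, b = d, np.zeros(n)
                p = wilcoxon_signed_rank(a, b)
                ranks = sps.rankdata(np.abs(d))
                w_obs = ranks[d > 0].sum()
                ws = [ranks[np.array(signs, bool)].sum()
                      for signs in itertools.product([0, 1], repeat=n)]
                ws = np.array(ws)
                p_low = (ws <= w_obs + 1e-9).mean()
                p_high = (ws >= w_obs - 1e-9).mean()
                expected = min(1.0, 2 * min(p_low, p_high))
                assert math.isclose(p, expected, abs_tol=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="exact").pvalue
        assert math.isclose(ours, ref, rel_tol=1e-9)

    def test_exact_and_normal_branches_agree_at_boundary(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.3, 1, size=25)
        b = rng.normal(0.0, 1, size=25)
        exact = wilcoxon_signed_rank(a, b, exact_max_n=25)
        approx = wilcoxon_signed_rank(a, b, exact_max_n=0)
        assert abs(exact - approx) < 0.01


class TestStability:
    def _matrices(self, seed=0, shift_row=None, n_subjects=20, factor=4.0):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(3, 1, size=30)
        t1 = pd.DataFrame(rng.poisson(mu[:, None], size=(30, n_subjects)),
                          index=[f"m{i}" for i in range(30)],
                          columns=[f"S{j}" for j in range(n_subjects)])
        mu2 = mu.copy()
        if shift_row is not None:
            mu2[shift_row] *= factor
        t2 = pd.DataFrame(rng.poisson(mu2[:, None], size=(30, n_subjects)),
                          index=t1.index, columns=t1.columns)
        return t1, t2

    def test_identical_matrices(self):
        t1, _ = self._matrices()
        rep = stability_report(t1, t1.copy())
        assert np.allclose(rep.per_subject["scc"], 1.0)
        assert (rep.per_mirna["wilcoxon_p"] == 1.0).all()

    def test_independent_profiles_center_near_zero(self):
        rng = np.random.default_rng(6)
        t1 = pd.DataFrame(rng.poisson(20, size=(60, 8)), columns=list("abcdefgh"))
        t2 = pd.DataFrame(rng.poisson(20, size=(60, 8)), columns=list("abcdefgh"))
        rep = stability_report(t1, t2)
        assert rep.per_subject["scc"].abs().mean() < 0.25

    def test_planted_shift_recovered(self):
        t1, t2 = self._matrices(seed=7, shift_row=4)
        rep = stability_report(t1, t2, mirna_subset=["m3", "m4", "m5"])
        pvals = rep.per_mirna.set_index("mirna")["wilcoxon_p"]
        assert pvals["m4"] < 0.01
        assert pvals["m3"] > 0.05 and pvals["m5"] > 0.05

    def test_no_shared_subjects_errors(self):
        t1 = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        t2 = pd.DataFrame(np.ones((5, 4)), columns=list("wxyz"))
        with pytest.raises(ValueError):
            stability_report(t1, t2)
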