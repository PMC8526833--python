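import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import faecomir as fm
from faecomir.diffexp import (
    DesignSpec,
    bh_adjust,
    call_demirnas,
    continuous_scc,
    estimate_dispersion,
    heatmap_matrix,
    nb_wald_row,
    run_de,
)
from faecomir.quantify import CountMatrix


def _cells(n, k=2):
    return pd.Series([f"c{i % k}" for i in range(n)])


class TestDispersion:
    def test_poisson_row_hits_floor_region(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(50, size=1000)
        a = estimate_dispersion(y, _cells(1000), pd.Series(np.ones(1000)))
        assert a < 0.02

    def test_nb_row_estimator_consistency(self):
        rng = np.random.default_rng(1)
        alpha = 0.5
        mu = 100.0
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=500))
        a = estimate_dispersion(y, _cells(500), pd.Series(np.ones(500)))
        assert 0.3 < a < 0.7

    def test_constant_row_floors(self):
        y = np.full(50, 7)
        a = estimate_dispersion(y, _cells(50), pd.Series(np.ones(50)))
        assert a <= 1e-6

    def test_degenerate_cells_fall_back_pooled(self, caplog):
        y = np.array([3, 4, 5, 6])
        cells = pd.Series(["a", "b", "c", "d"])  # every cell has 1 sample
        with caplog.at_level("WARNING", logger="faecomir"):
            a = estimate_dispersion(y, cells, pd.Series(np.ones(4)))
        assert a >= 0 and "pooled" in caplog.text


class TestNBWald:
    def test_poisson_limit_matches_poisson_glm(self):
        """At alpha ~ 0 and large counts, W agrees with a Poisson-regression
        oracle within 1%."""
        rng = np.random.default_rng(2)
        n = 200
        x = (np.arange(n) % 2).astype(float)
        mu = np.exp(5.0 + 0.4 * x)
        y = rng.poisson(mu)
        X = pd.DataFrame({"intercept": np.ones(n), "contrast": x})
        offset = np.zeros(n)
        ours = nb_wald_row(y.astype(float), X, offset, alpha_hat=0.0)
        oracle = sm.GLM(y, X.to_numpy(),
                        family=sm.families.Poisson(), offset=offset).fit()
        w_oracle = oracle.params[1] / oracle.bse[1]
        assert abs(ours["wald"] - w_oracle) / abs(w_oracle) < 0.01

    def test_separated_contrast_flagged(self):
        n = 40
        x = (np.arange(n) < 20).astype(float)
        y = np.where(x > 0, 0.0, 50.0)
        X = pd.DataFrame({"intercept": np.ones(n), "contrast": x})
        res = nb_wald_row(y, X, np.zeros(n), alpha_hat=0.1)
        assert res["flag"] in ("separated", "fit_error")


class TestBH:
    def test_hand_applied_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_missing_p_stays_missing(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_definitional_oracle(self, ps):
        """Step-up BH computed directly from the definition."""
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        oracle = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, ps[i] * m / rank_from_top)
            oracle[i] = running
        assert np.allclose(q, oracle)
        assert (q >= np.asarray(ps) - 1e-12).all()


class TestDECall:
    @pytest.mark.parametrize("q,m1,m2,expected", [
        (0.04, 12.0, 3.0, True),     # both criteria met
        (0.04, 8.0, 9.0, False),     # abundance filter fails
        (0.06, 50.0, 50.0, False),   # significance filter fails
    ])
    def test_dual_criterion(self, q, m1, m2, expected):
        df = pd.DataFrame({"mirna": ["m"], "log2fc": [1.0], "q": [q],
                           "median_ref": [m1], "median_test": [m2]})
        out = call_demirnas(df)
        assert bool(out["is_de"].iloc[0]) is expected


class TestRunDE:
    def _null_setup(self, n_prec=50, n_sub=60, seed=0):
        ref = fm.simulate_reference(n_prec, 0.7, seed=seed)
        cohort = fm.categorize_cohort(fm.simulate_cohort(n_sub, seed=seed + 1))
        cfg = fm.SimulationConfig(n_subjects=n_sub, seed=seed + 2,
                                  dispersion=0.3)
        sim = fm.simulate_counts(ref, cohort, [], cfg)
        return ref, cohort, sim

    def test_null_q_values_make_no_calls(self):
        _ref, cohort, sim = self._null_setup()
        design = DesignSpec("sex", "female", "male",
                            adjustment_covariates=["age"])
        res = run_de(sim.matrix, cohort, design)
        assert res["is_de"].sum() <= 2

    def test_planted_effect_estimate_recovered(self):
        ref = fm.simulate_reference(40, 0.7, seed=5)
        cohort = fm.categorize_cohort(fm.simulate_cohort(
            200, marginals={"sex": {"female": 0.5, "male": 0.5}}, seed=6))
        base = fm.draw_baseline(80, sigma=1.0, seed=7)
        cfg = fm.SimulationConfig(n_subjects=200, seed=8, dispersion=0.3,
                                  baseline_abundance=base)
        expressed = fm.expressed_mature_names(ref, base, cfg)
        planted = expressed[:5]
        eff = fm.EffectSpec("sex", ("female", "male"), planted, [1.5] * 5)
        sim = fm.simulate_counts(ref, cohort, [eff], cfg)
        design = DesignSpec("sex", "female", "male",
                            adjustment_covariates=["age"])
        res = run_de(sim.matrix, cohort, design).set_index("mirna")
        mean_lfc = res.loc[planted, "log2fc"].mean()
        assert abs(mean_lfc - 1.5) < 0.2
        assert res.loc[planted, "is_de"].all()

    def test_sex_stratified_reuses_same_path(self):
        _ref, cohort, sim = self._null_setup(seed=9)
        females = cohort[cohort["sex"] == "female"]
        fmatrix = sim.matrix.subset_samples(
            [s for s in sim.matrix.sample_ids
             if s in set(females.index.astype(str))])
        design = DesignSpec("coffee_class", "non_drinker", "high",
                            adjustment_covariates=["age"])
        res = run_de(fmatrix, females, design)
        assert res.attrs["n_ref"] + res.attrs["n_test"] <= len(females)

    def test_missing_covariate_subjects_dropped(self):
        _ref, cohort, sim = self._null_setup(seed=12)
        cohort = cohort.copy()
        cohort.loc[cohort.index[0], "age"] = np.nan
        design = DesignSpec("sex", "female", "male",
                            adjustment_covariates=["age"])
        res = run_de(sim.matrix, cohort, design)
        assert res.attrs["n_ref"] + res.attrs["n_test"] == len(cohort) - 1


class TestContinuousSCC:
    def test_planted_monotone_mirna_classified_increasing(self):
        rng = np.random.default_rng(10)
        n = 100
        age = rng.uniform(20, 80, n)
        counts = pd.DataFrame(
            rng.poisson(50, size=(10, n)),
            index=[f"m{i}" for i in range(10)],
            columns=[f"S{j}" for j in range(n)])
        counts.iloc[0] = np.round(20 + age + rng.normal(0, 3, n)).astype(int)
        matrix = CountMatrix(counts, size_factors=pd.Series(
            1.0, index=counts.columns))
        res = continuous_scc(matrix, pd.Series(age, index=counts.columns))
        res = res.set_index("mirna")
        assert res.loc["m0", "category"] == "increasing"
        assert res.loc["m0", "q"] < 0.05

    def test_scc_exactly_at_band_is_unaltered(self):
        # ranks (1,2,3,4) vs (3,2,1,4): rho = 1 - 6*8/60 = 0.2 exactly
        counts = pd.DataFrame(
            [[30, 20, 10, 40], [15, 15, 15, 15]],
            index=["m0", "m1"], columns=list("abcd"))
        matrix = CountMatrix(counts, size_factors=pd.Series(
            1.0, index=counts.columns))
        res = continuous_scc(matrix, pd.Series([1.0, 2.0, 3.0, 4.0],
                                               index=counts.columns))
        res = res.set_index("mirna")
        assert math.isclose(res.loc["m0", "scc"], 0.2)
        assert res.loc["m0", "category"] == "unaltered"

    def test_permuted_covariate_mostly_unaltered(self):
        rng = np.random.default_rng(11)
        n = 300
        counts = pd.DataFrame(rng.poisson(40, size=(50, n)),
                              columns=[f"S{j}" for j in range(n)])
        counts.index = [f"m{i}" for i in range(50)]
        matrix = CountMatrix(counts, size_factors=pd.Series(
            1.0, index=counts.columns))
        res = continuous_scc(matrix, pd.Series(rng.uniform(0, 1, n),
                                               index=counts.columns))
        assert (res["category"] == "unaltered").mean() > 0.95


class TestHeatmap:
    def _matrix(self, data):
        df = pd.DataFrame(data, columns=[f"S{j}" for j in
                                         range(np.shape(data)[1])])
        df.index = [f"m{i}" for i in range(np.shape(data)[0])]
        return CountMatrix(df.astype(int),
                           size_factors=pd.Series(1.0, index=df.columns))

    def test_rows_are_zscored(self):
        rng = np.random.default_rng(12)
        m = self._matrix(rng.poisson(30, size=(6, 10)))
        hm = heatmap_matrix(m, list(m.mature_names))
        z = hm.zscores.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)

    def test_identical_rows_merge_first(self):
        data = [[10, 20, 30, 40], [10, 20, 30, 40], [40, 30, 20, 10],
                [5, 50, 5, 50]]
        m = self._matrix(data)
        hm = heatmap_matrix(m, list(m.mature_names))
        first_merge = set(hm.row_linkage[0, :2].astype(int))
        assert first_merge == {0, 1}

    def test_first_merge_matches_min_distance_oracle(self):
        rng = np.random.default_rng(13)
        m = self._matrix(rng.poisson(25, size=(4, 6)))
        hm = heatmap_matrix(m, list(m.mature_names))
        z = hm.zscores.to_numpy()
        best, pair = np.inf, None
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.linalg.norm(z[i] - z[j])
                if d < best:
                    best, pair = d, {i, j}
        assert set(hm.row_linkage[0, :2].astype(int)) == pair

    def test_zero_variance_row_flagged(self):
        data = [[7, 7, 7, 7], [1, 5, 9, 13]]
        m = self._matrix(data)
        hm = heatmap_matrix(m, list(m.mature_names))
        assert hm.degenerate_rows == ["m0"]
        assert (hm.zscores.loc["m0"] == 0).all()
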