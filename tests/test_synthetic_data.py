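import io

import numpy as np
import pandas as pd
import pytest

import faecomir as fm
from faecomir.io_formats import write_reference
from faecomir.synthetic_data import (
    EffectSpec,
    SimulationConfig,
    draw_baseline,
    simulate_alignments,
    simulate_cohort,
    simulate_counts,
    simulate_reference,
    simulate_repeated_samples,
)


class TestSimulateReference:
    def test_annotated_fraction_extremes(self):
        all_armed = simulate_reference(10, 1.0, seed=1)
        assert all(all_armed.arm_annotation(p) is not None
                   for p in all_armed.precursor_ids)
        none_armed = simulate_reference(10, 0.0, seed=1)
        assert all(none_armed.arm_annotation(p) is None
                   for p in none_armed.precursor_ids)

    def test_same_seed_byte_identical(self, tmp_path):
        for i, seed in enumerate([5, 5]):
            ref = simulate_reference(20, 0.5, seed=seed)
            write_reference(ref, tmp_path / f"r{i}.fa", tmp_path / f"a{i}.tsv")
        assert (tmp_path / "r0.fa").read_bytes() == (tmp_path / "r1.fa").read_bytes()
        assert (tmp_path / "a0.tsv").read_bytes() == (tmp_path / "a1.tsv").read_bytes()

    def test_precursor_lengths_and_arm_sizes(self):
        ref = simulate_reference(50, 1.0, seed=2)
        for p in ref.precursors:
            assert 60 <= len(p) <= 120
            ann = ref.arm_annotation(p.precursor_id)
            for iv in (ann.arm5p, ann.arm3p):
                assert 18 <= iv[1] - iv[0] <= 25


class TestSimulateCounts:
    def test_planted_fold_change_recovered_in_group_means(self):
        """log2fc = 2 between smokers and never-smokers: the mean-count ratio
        approaches 4 at large n (law of large numbers)."""
        ref = simulate_reference(3, 1.0, seed=3)
        cohort = fm.categorize_cohort(simulate_cohort(10000, seed=4))
        target = ref.mature_names[0]
        eff = EffectSpec("smoking", ("never", "heavy_current"), [target], [2.0])
        cfg = SimulationConfig(n_subjects=10000, seed=5,
                               library_size_mean=2e5, mirna_fraction=0.01,
                               dispersion=0.2)
        sim = simulate_counts(ref, cohort, [eff], cfg)
        norm = sim.matrix.counts / sim.true_size_factors
        heavy = cohort.index[cohort["smoking"] == "heavy_current"].astype(str)
        never = cohort.index[cohort["smoking"] == "never"].astype(str)
        ratio = norm.loc[target, heavy].mean() / norm.loc[target, never].mean()
        assert 3.6 < ratio < 4.4

    def test_zero_dispersion_is_poisson(self):
        """alpha = 0: per-cell variance ~ mean over many draws."""
        ref = simulate_reference(2, 1.0, seed=6)
        cohort = simulate_cohort(10000, seed=7)
        cfg = SimulationConfig(n_subjects=10000, seed=8, dispersion=0.0,
                               library_size_mean=1e5, mirna_fraction=0.01,
                               library_size_log_sd=0.0)
        sim = simulate_counts(ref, cohort, [], cfg)
        row = sim.matrix.counts.iloc[0].to_numpy(dtype=float)
        assert abs(row.var(ddof=1) / row.mean() - 1.0) < 0.1

    def test_nb_moments(self):
        """variance ~ mean + alpha * mean^2 at alpha = 0.5."""
        ref = simulate_reference(2, 1.0, seed=9)
        cohort = simulate_cohort(10000, seed=10)
        cfg = SimulationConfig(n_subjects=10000, seed=11, dispersion=0.5,
                               library_size_mean=1e5, mirna_fraction=0.01,
                               library_size_log_sd=0.0)
        sim = simulate_counts(ref, cohort, [], cfg)
        row = sim.matrix.counts.iloc[0].to_numpy(dtype=float)
        m = row.mean()
        expected_var = m + 0.5 * m * m
        assert 0.8 < row.var(ddof=1) / expected_var < 1.2

    def test_truth_ledger_lists_every_planted_effect(self):
        ref = simulate_reference(5, 1.0, seed=12)
        cohort = simulate_cohort(20, seed=13)
        effects = [
            EffectSpec("sex", ("female", "male"), ref.mature_names[:3],
                       [1.0, -1.0, 2.0]),
            EffectSpec("age", "continuous", ref.mature_names[3:5], [0.5, 0.5]),
        ]
        cfg = SimulationConfig(n_subjects=20, seed=14)
        sim = simulate_counts(ref, cohort, effects, cfg)
        assert len(sim.truth) == 5
        assert set(sim.truth["variable"]) == {"sex", "age"}

    def test_effect_on_missing_covariate_errors(self):
        ref = simulate_reference(2, 1.0, seed=15)
        cohort = simulate_cohort(10, seed=16)
        eff = EffectSpec("nope", ("a", "b"), [ref.mature_names[0]], [1.0])
        with pytest.raises(ValueError, match="missing covariate"):
            simulate_counts(ref, cohort, [eff],
                            SimulationConfig(n_subjects=10, seed=17))

    def test_determinism(self):
        ref = simulate_reference(4, 0.5, seed=18)
        cohort = simulate_cohort(12, seed=19)
        cfg = SimulationConfig(n_subjects=12, seed=20)
        a = simulate_counts(ref, cohort, [], cfg)
        b = simulate_counts(ref, cohort, [], cfg)
        pd.testing.assert_frame_equal(a.matrix.counts, b.matrix.counts)


class TestSimulateAlignments:
    def test_requested_counts_placed_in_arm(self, toy_reference):
        recs = simulate_alignments({"mirA-5p": 3}, toy_reference, seed=1)
        assert len(recs) == 3
        for r in recs:
            assert r.precursor_id == "mirA" and 0 <= r.start and r.end <= 22

    def test_empty_counts_empty_list(self, toy_reference):
        assert simulate_alignments({}, toy_reference, seed=1) == []

    def test_same_seed_identical(self, toy_reference):
        a = simulate_alignments({"mirB-3p": 5}, toy_reference, seed=7)
        b = simulate_alignments({"mirB-3p": 5}, toy_reference, seed=7)
        assert a == b


class TestRepeatedSamples:
    def _simulate(self, drift_sd, seed=30):
        ref = simulate_reference(60, 0.6, seed=21)
        cohort = simulate_cohort(24, seed=22)
        cfg = SimulationConfig(n_subjects=24, seed=23,
                               library_size_mean=2e6, mirna_fraction=0.01)
        sim = simulate_counts(ref, cohort, [], cfg)
        repeat = simulate_repeated_samples(cohort, sim, n_repeat_subjects=6,
                                           drift_sd=drift_sd, seed=seed)
        return sim, repeat

    def test_default_six_repeat_subjects(self):
        sim, repeat = self._simulate(0.1)
        assert len(repeat.sample_ids) == 6
        assert set(repeat.sample_ids) <= set(sim.matrix.sample_ids)

    def test_zero_drift_gives_high_paired_correlation(self):
        from faecomir.variability import spearman
        sim, repeat = self._simulate(0.0)
        for s in repeat.sample_ids:
            rho, _ = spearman(sim.matrix.counts[s], repeat.counts[s])
            assert rho > 0.85

    def test_same_seed_identical(self):
        _, a = self._simulate(0.2, seed=31)
        _, b = self._simulate(0.2, seed=31)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestBaselineHelpers:
    def test_expressed_names_threshold(self):
        ref = simulate_reference(10, 1.0, seed=24)
        base = draw_baseline(20, sigma=2.0, seed=25)
        cfg = SimulationConfig(n_subjects=10, seed=26,
                               library_size_mean=1e6, mirna_fraction=0.01)
        names = fm.expressed_mature_names(ref, base, cfg, min_mean=10)
        mu = base / base.sum() * 1e6 * 0.01
        expected = [n for n, m in zip(ref.mature_names, mu) if m >= 10]
        assert names == expected
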