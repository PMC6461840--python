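"""Differential-expression stage: normalization, tests, BH, onset filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmsom.errors import DegenerateInputError
from ecmsom.expression import (
    adjust_bh,
    normalize_counts,
    select_onset_genes,
    size_factors,
)
from ecmsom.expression import test_pairwise as run_pairwise
from ecmsom.expression import test_time_course as run_time_course
from ecmsom.synthetic import GeneTemplate, SimDesign, simulate_counts


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [200], [3000]], (1, 4)))
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_gets_double_factor(self):
        base = np.array([[10, 10], [200, 200], [3000, 3000]], float)
        base[:, 1] *= 2
        f = size_factors(pd.DataFrame(base))
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_three_gene_worked_example(self):
        counts = pd.DataFrame([[100, 200], [10, 20], [1000, 2000]])
        f = size_factors(counts)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_common_gene_raises_unless_fallback(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(DegenerateInputError):
            size_factors(counts)
        f = size_factors(counts, fallback="pseudo-reference")
        assert (f > 0).all()

    def test_normalization_restores_identical_columns(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(50, 1)).astype(float)
        counts = pd.DataFrame(base * np.array([0.5, 1.0, 2.0, 4.0]))
        norm = normalize_counts(counts)
        spread = norm.max(axis=1) - norm.min(axis=1)
        np.testing.assert_allclose(spread, 0.0, atol=1e-9)


class TestTimeCourse:
    def test_null_rejection_rate_nominal(self, null_counts):
        """Type-I error of the time-course test at 0.05 over 5000 null
        genes stays within 0.05 +/- 0.02."""
        counts, meta = null_counts
        tc = run_time_course(counts, meta)
        rate = float((tc["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_for_eightfold_step(self):
        """An 8-fold step at n = 3, base mean 100, is detected at the
        0.01 level in >90% of simulated genes."""
        tpl = ([GeneTemplate(gene_id=f"n{i:04d}", pattern=("S", "S", "S"),
                             base_mean=100.0, dispersion=0.1)
                for i in range(1800)]
               + [GeneTemplate(gene_id=f"s{i:04d}", pattern=("U", "S", "S"),
                               lfc_magnitude=3.0, base_mean=100.0,
                               dispersion=0.1) for i in range(200)])
        counts, meta = simulate_counts(SimDesign(seed=21), tpl)
        tc = run_time_course(counts, meta)
        power = float((tc.loc[[t.gene_id for t in tpl[1800:]], "p"] < 0.01).mean())
        assert power > 0.9

    def test_constant_noiseless_gene_keeps_p_near_one(self):
        tpl = [GeneTemplate(gene_id="g", pattern=("S", "S", "S"),
                            base_mean=50.0, dispersion=0.0)]
        counts, meta = simulate_counts(SimDesign(seed=5), tpl,
                                       library_factor_range=(1.0, 1.0))
        counts.iloc[0] = 50  # exactly constant, no Poisson noise
        tc = run_time_course(counts, meta)
        assert tc["p"].iloc[0] > 0.99

    def test_all_zero_gene_flagged_untestable(self, null_counts):
        counts, meta = null_counts
        counts = counts.head(50).copy()
        counts.iloc[0] = 0
        tc = run_time_course(counts, meta)
        assert bool(tc["untestable"].iloc[0])
        assert tc["p"].iloc[0] == 1.0

    def test_scaling_one_sample_absorbed_by_size_factors(self, null_counts):
        counts, meta = null_counts
        counts = counts.head(300)
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 3).astype(int)
        p1 = run_time_course(counts, meta)["p"]
        p2 = run_time_course(scaled, meta)["p"]
        # same ranking and near-identical p-values after normalization
        assert np.corrcoef(np.log10(p1 + 1e-300), np.log10(p2 + 1e-300))[0, 1] > 0.99

    def test_empirical_fdr_controlled(self, cohort, cohort_time_course):
        """Among time-DEG calls on the default signal-plus-null cohort the
        realized false-discovery proportion stays below 2x nominal 0.01."""
        truth = cohort["truth"]
        calls = cohort_time_course[cohort_time_course["time_deg"]].index
        false = sum(truth.loc[g, "pattern"] == "SSS" for g in calls)
        assert len(calls) > 0
        assert false / len(calls) <= 0.02


class TestPairwise:
    def test_null_rejection_rate_nominal(self, null_counts):
        counts, meta = null_counts
        pw = run_pairwise(counts, meta, "t2", "t1")
        rate = float((pw["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_twofold_lfc_estimated_without_bias(self):
        tpl = ([GeneTemplate(gene_id=f"n{i:04d}", pattern=("S", "S", "S"),
                             base_mean=100.0, dispersion=0.02)
                for i in range(1500)]
               + [GeneTemplate(gene_id=f"s{i:04d}", pattern=("U", "S", "S"),
                               lfc_magnitude=1.0, base_mean=2000.0,
                               dispersion=0.02) for i in range(500)])
        counts, meta = simulate_counts(SimDesign(seed=8), tpl)
        pw = run_pairwise(counts, meta, "t2", "t1")
        sig_lfc = pw.loc[[t.gene_id for t in tpl[1500:]], "lfc"]
        assert abs(sig_lfc.mean() - 1.0) < 0.2

    def test_gene_absent_at_reference_keeps_finite_lfc(self, null_counts):
        counts, meta = null_counts
        counts = counts.head(20).copy()
        t1_cols = meta.loc[meta["time_point"] == "t1", "sample_id"]
        counts.loc[counts.index[0], t1_cols] = 0
        pw = run_pairwise(counts, meta, "t2", "t1")
        assert np.isfinite(pw["lfc"].iloc[0])
        assert not pw["untestable"].iloc[0]

    def test_all_zero_both_groups_untestable(self, null_counts):
        counts, meta = null_counts
        counts = counts.head(20).copy()
        cols = meta.loc[meta["time_point"].isin(["t1", "t2"]), "sample_id"]
        counts.loc[counts.index[0], cols] = 0
        pw = run_pairwise(counts, meta, "t2", "t1")
        assert bool(pw["untestable"].iloc[0])


class TestAdjustBH:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_never_below_raw_and_monotone_in_sorted_order(self, pvals):
        p = np.array(pvals)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestOnsetGenes:
    def _frames(self):
        de = pd.DataFrame(
            {"lfc": [2.0, 0.5, 2.0, 2.0],
             "p_adj": [1e-5, 1e-5, 0.5, 1e-5]},
            index=["hit", "low_fold", "not_sig", "low_expr"])
        expr = pd.Series([1000.0, 1000.0, 1000.0, 1.0],
                         index=de.index)
        return de, expr

    def test_three_way_filter(self):
        de, expr = self._frames()
        assert select_onset_genes(de, expr) == {"hit"}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            select_onset_genes(pd.DataFrame(columns=["lfc", "p_adj"]),
                               pd.Series(dtype=float))

    def test_seeded_onset_cohort_recovered(self):
        """50 strongly induced, highly expressed genes among 5000 are all
        recovered with fewer than 5 false positives."""
        rng = np.random.default_rng(0)
        tpl = [GeneTemplate(gene_id=f"n{i:05d}", pattern=("S", "S", "S"),
                            base_mean=float(np.exp(rng.normal(np.log(100), 1.0))),
                            dispersion=0.02) for i in range(4950)]
        tpl += [GeneTemplate(gene_id=f"o{i:03d}", pattern=("U", "S", "S"),
                             lfc_magnitude=3.0,
                             base_mean=float(np.exp(rng.normal(np.log(2000), 0.3))),
                             dispersion=0.02) for i in range(50)]
        counts, meta = simulate_counts(SimDesign(seed=3), tpl)
        tc = run_time_course(counts, meta)
        pw = run_pairwise(counts, meta, "t2", "t1")
        onset = select_onset_genes(pw, tc["mean_t2"])
        seeded = {f"o{i:03d}" for i in range(50)}
        assert seeded <= onset
        assert len(onset - seeded) < 5
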