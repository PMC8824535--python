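"""Spike-in normalization and the exact nonparametric test battery against
literal enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirrank import qpcr_stats as qs
from mirrank import synthetic_data as sd

NAN = float("nan")


def wilcoxon_oracle(d):
    """Two-sided signed-rank p by literal enumeration of all 2^n sign
    patterns on the mid-ranks of |d| (zeros dropped beforehand)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


def mann_whitney_oracle(a, b):
    """Two-sided exact p by enumerating all group labelings; U computed by
    pair counting (not rank sums) for independence."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    na = a.size

    def u_stat(idx_a):
        aa = combined[list(idx_a)]
        bb = np.delete(combined, list(idx_a))
        gt = (aa[:, None] > bb[None, :]).sum()
        eq = (aa[:, None] == bb[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(range(na))
    us = np.array([u_stat(c) for c in itertools.combinations(range(combined.size), na)])
    p_low = np.mean(us <= u_obs + 1e-9)
    p_high = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestRelativeExpression:
    def test_zero_delta_gives_unit_expression(self):
        m = qs.CtMeasurement("s1", "hsa-miR-126", "pre", [25, 25, 25], [25, 25, 25])
        e = qs.relative_expression(m)
        assert e.rel_expr == pytest.approx(1.0)
        assert e.log_expr == pytest.approx(0.0)

    def test_analytic_delta_three(self):
        m = qs.CtMeasurement("s1", "hsa-miR-126", "pre", [25, 25, 25], [22, 22, 22])
        e = qs.relative_expression(m)
        assert e.delta_ct == pytest.approx(3.0)
        assert e.rel_expr == pytest.approx(0.125)
        assert e.log_expr == pytest.approx(-e.delta_ct)

    def test_partial_replicates_use_available_means(self):
        m = qs.CtMeasurement("s1", "hsa-miR-126", "pre", [24, 26, NAN], [22, NAN, NAN])
        e = qs.relative_expression(m)
        assert e.delta_ct == pytest.approx(3.0)

    def test_all_undetermined_is_non_detectable(self):
        m = qs.CtMeasurement("s1", "hsa-miR-106a-5p", "pre", [NAN] * 3, [22, 22, 22])
        e = qs.relative_expression(m)
        assert not e.detectable and math.isnan(e.rel_expr)

    def test_missing_normalizer_is_error(self):
        m = qs.CtMeasurement("s1", "hsa-miR-126", "pre", [25, 25, 25], [NAN] * 3)
        with pytest.raises(ValueError, match="normalizer missing"):
            qs.relative_expression(m)

    def test_ct_outside_range_rejected(self):
        with pytest.raises(ValueError):
            qs.CtMeasurement("s1", "m", "pre", [46.0, 25, 25], [22, 22, 22])


class TestPairedTest:
    def test_all_zero_differences_p_one(self):
        res = qs.paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.n == 0

    def test_five_positive_differences_exact(self):
        # all 5 differences positive: two-sided p = 2/32
        res = qs.paired_test([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2 / 32)
        assert res.direction == "increase"

    def test_matches_sign_enumeration_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 9))
            pre = rng.normal(size=n)
            post = pre + rng.normal(size=n)
            res = qs.paired_test(pre, post)
            assert res.p_value == pytest.approx(wilcoxon_oracle(post - pre), abs=1e-12)

    def test_exact_handles_tied_magnitudes(self):
        pre = np.zeros(6)
        post = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        res = qs.paired_test(pre, post)
        assert res.p_value == pytest.approx(wilcoxon_oracle(post - pre), abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            qs.paired_test([1.0], [2.0])

    def test_missing_pairs_dropped(self):
        res = qs.paired_test([1, 2, NAN, 4, 5], [2, 3, 9, 5, 6])
        assert res.n == 4

    def test_approximation_continuous_with_exact(self, rng):
        # at n just above/below the exact cutoff the p-values should be close
        pre = rng.normal(size=21)
        post = pre + rng.normal(loc=0.5, size=21)
        exact_like = qs.paired_test(pre, post, exact_max_n=21)
        approx = qs.paired_test(pre, post, exact_max_n=5)
        assert approx.p_value == pytest.approx(exact_like.p_value, rel=0.25, abs=0.01)


class TestUnpairedTest:
    def test_complete_separation_3v3(self):
        res = qs.unpaired_test([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(2 / 20)
        assert res.group_sizes == (3, 3)

    def test_identical_multisets_symmetric(self):
        res = qs.unpaired_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n_a*n_b/2
        assert res.p_value == pytest.approx(1.0)

    def test_matches_labeling_enumeration_oracle(self, rng):
        for _ in range(10):
            na = int(rng.integers(3, 7))
            nb = int(rng.integers(3, 7))
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.uniform(-1, 1), size=nb)
            res = qs.unpaired_test(a, b)
            assert res.p_value == pytest.approx(mann_whitney_oracle(a, b), abs=1e-12)

    def test_oracle_agreement_with_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 3.0, 7.0]
        res = qs.unpaired_test(a, b)
        assert res.p_value == pytest.approx(mann_whitney_oracle(a, b), abs=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            qs.unpaired_test([1.0], [1, 2, 3])


class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        res = qs.spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        res = qs.spearman_correlation([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert res.statistic == pytest.approx(-1.0)

    def test_rho_equals_pearson_of_midranks_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 9.0, 9.0, 10.0])
        y = rng.normal(size=10)
        res = qs.spearman_correlation(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = qs.spearman_correlation(x, y)
        rho, p = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_exact_permutation_small_n(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = qs.spearman_correlation(x, y)
        # independent check: scipy's exact permutation distribution
        ref = stats.spearmanr(x, y)
        exact = stats.permutation_test(
            (y,), lambda yy: stats.spearmanr(x, yy).statistic,
            permutation_type="pairings", n_resamples=math.inf,
            alternative="two-sided",
        )
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(exact.pvalue, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            qs.spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestTransformInvariance:
    def test_log_base_cannot_affect_any_headline_statistic(self, rng):
        # log10(x) = c * log2(x): a positive rescaling, which preserves the
        # rank of |differences| (signed-rank) and all value ranks
        pre = np.log2(2.0 ** rng.normal(size=12))
        post = np.log2(2.0 ** rng.normal(loc=0.6, size=12))
        for base_change in (np.log10(2.0), np.log(2.0)):
            assert qs.paired_test(pre, post).p_value == pytest.approx(
                qs.paired_test(pre * base_change, post * base_change).p_value,
                abs=1e-12,
            )

    def test_rank_tests_invariant_under_monotone_transform(self, rng):
        # Mann-Whitney and Spearman depend only on ranks, so the 2^-dCT and
        # log scales give identical results
        a, b = 2.0 ** rng.normal(size=8), 2.0 ** rng.normal(size=8)
        assert qs.unpaired_test(a, b).p_value == pytest.approx(
            qs.unpaired_test(np.log2(a), np.log2(b)).p_value, abs=1e-12
        )
        x, y = 2.0 ** rng.normal(size=10), rng.normal(size=10)
        assert qs.spearman_correlation(x, y).statistic == pytest.approx(
            qs.spearman_correlation(np.log2(x), y).statistic, abs=1e-12
        )


class TestDichotomize:
    def frame(self):
        return pd.DataFrame(
            {
                "hs_crp": [1.0, 2.0, 5.0, 6.0, 8.0, 3.0, 9.0, 4.0],
                "log_expr": [0.5, 1.0, 0.8, -1.0, -2.0, 0.2, -1.5, 0.9],
            }
        )

    def test_boundary_value_goes_to_low_group(self):
        res = qs.dichotomize_and_compare(self.frame(), "hs_crp", 5.0)
        assert res.group_sizes == (5, 3)  # 5.0 counted as low

    def test_all_below_threshold_degenerate(self):
        with pytest.raises(ValueError, match="degenerate split"):
            qs.dichotomize_and_compare(self.frame(), "hs_crp", 100.0)

    def test_planted_shift_direction_detected(self):
        df = pd.DataFrame(
            {
                "lactate_max": [2, 2, 3, 3, 6, 6, 7, 7],
                "log_expr": [2.0, 2.2, 1.9, 2.1, -1.0, -1.2, -0.9, -1.1],
            }
        )
        res = qs.dichotomize_and_compare(df, "lactate_max", 4.0)
        # low-lactate group has higher expression
        assert res.direction == "increase" and res.p_value < 0.05


class TestSummarizeCohort:
    def test_medians_match_percentile_oracle(self, small_config):
        cohort, ct, _ = sd.gen_cohort(small_config)
        ms = [
            qs.CtMeasurement(r.subject_id, r.mirna, r.timepoint,
                             [r.ct_1, r.ct_2, r.ct_3],
                             [r.spike_1, r.spike_2, r.spike_3])
            for r in ct.itertuples(index=False)
        ]
        expr = qs.expressions_from_ct(ms)
        summary = qs.summarize_cohort(cohort, expr)
        crp = summary[summary["variable"] == "hs_crp"].iloc[0]
        post = cohort.loc[cohort["timepoint"] == "post", "hs_crp"].to_numpy()
        assert crp["median_post"] == pytest.approx(np.percentile(post, 50))
        assert crp["q1_post"] == pytest.approx(np.percentile(post, 25))
        assert crp["q3_post"] == pytest.approx(np.percentile(post, 75))

    def test_undetectable_mirna_excluded(self, small_config):
        cohort, ct, truth = sd.gen_cohort(small_config)
        ms = [
            qs.CtMeasurement(r.subject_id, r.mirna, r.timepoint,
                             [r.ct_1, r.ct_2, r.ct_3],
                             [r.spike_1, r.spike_2, r.spike_3])
            for r in ct.itertuples(index=False)
        ]
        summary = qs.summarize_cohort(cohort, qs.expressions_from_ct(ms))
        assert not set(truth.undetectable) & set(summary["variable"])

    def test_single_subject_tests_skipped(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["s1", "s1"],
                "timepoint": ["pre", "post"],
                "hs_crp": [1.0, 4.0],
            }
        )
        expr = pd.DataFrame(
            columns=["subject_id", "mirna", "timepoint", "delta_ct",
                     "rel_expr", "log_expr", "detectable"]
        )
        summary = qs.summarize_cohort(cohort, expr)
        row = summary.iloc[0]
        assert row["median_pre"] == 1.0 and row["median_post"] == 4.0
        assert math.isnan(row["p_value"])

    def test_column_order_stable(self, small_config):
        cohort, ct, _ = sd.gen_cohort(small_config)
        ms = [
            qs.CtMeasurement(r.subject_id, r.mirna, r.timepoint,
                             [r.ct_1, r.ct_2, r.ct_3],
                             [r.spike_1, r.spike_2, r.spike_3])
            for r in ct.itertuples(index=False)
        ]
        s1 = qs.summarize_cohort(cohort, qs.expressions_from_ct(ms))
        s2 = qs.summarize_cohort(cohort, qs.expressions_from_ct(ms))
        pd.testing.assert_frame_equal(s1, s2)


def test_normality_gate_modes(rng):
    normal = rng.normal(size=50)
    skewed = np.exp(rng.normal(size=50) * 2)
    assert qs.choose_location_test(normal) == "parametric"
    assert qs.choose_location_test(skewed) == "nonparametric"


def test_paired_power_at_study_size():
    """Planted 2.0 post/pre fold change at n=23: signed-rank rejection rate
    >= 80% (the study's design condition; replicate noise 0.15 cycles)."""
    from conftest import null_cohort_config

    rejections = 0
    n_reps = 500
    for rep in range(n_reps):
        cfg = null_cohort_config(seed=40_000 + rep)
        cfg.planted_fold_changes = {"hsa-miR-126": 2.0}
        _, ct, _ = sd.gen_cohort(cfg)
        wide = ct.assign(ct_mean=ct[["ct_1", "ct_2", "ct_3"]].mean(axis=1),
                         sp_mean=ct[["spike_1", "spike_2", "spike_3"]].mean(axis=1))
        wide["log_expr"] = -(wide["ct_mean"] - wide["sp_mean"])
        piv = wide.pivot_table(index="subject_id", columns="timepoint",
                               values="log_expr")
        if qs.paired_test(piv["pre"], piv["post"]).p_value < 0.05:
            rejections += 1
    assert rejections / n_reps >= 0.80
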