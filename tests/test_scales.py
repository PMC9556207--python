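"""Scale severity bands, group assignment, summary statistics and t-tests."""

import numpy as np
import pytest
from scipy import stats as sps

from eegmusic import scales as S
from eegmusic.synth import gen_scale_cohort, gen_study_cohort


class TestSeverity:
    @pytest.mark.parametrize(
        "scale,score,band",
        [
            ("phq9", 7, "mild"),
            ("phq9", 0, "normal"),
            ("phq9", 27, "severe"),
            ("sds", 52, "normal"),
            ("sds", 53, "mild"),
            ("scl90", 26, "normal"),
            ("scl90", 27, "mild"),
        ],
    )
    def test_boundary_values(self, scale, score, band):
        assert S.classify_severity(scale, score) == band

    @pytest.mark.parametrize("scale", S.SCALES)
    def test_bands_partition_admissible_integers(self, scale):
        """Exhaustive integer sweep: exactly one band per admissible score,
        and band order is non-decreasing in severity."""
        lo, hi = S.SCALE_RANGES[scale]
        order = ["normal", "mild", "moderate", "moderately_severe", "severe"]
        last = 0
        for score in range(int(lo), int(hi) + 1):
            band = S.classify_severity(scale, score)  # raises if uncovered
            idx = order.index(band)
            assert idx >= last
            last = idx

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            S.classify_severity("phq9", 28)
        with pytest.raises(ValueError):
            S.classify_severity("sds", -1)


class TestAssignGroup:
    @pytest.mark.parametrize(
        "triple,will_train,expected",
        [
            ((5, 40, 2), False, "normal_control"),
            ((30, 55, 7), True, "feedback"),
            ((30, 55, 7), False, "depression_control"),
            ((20, 55, 7), False, "ineligible"),  # fails SCL-90 > 26
            ((30, 70, 7), True, "ineligible"),  # SDS outside [53, 62]
        ],
    )
    def test_criteria(self, triple, will_train, expected):
        assert S.assign_group(*triple, will_train=will_train) == expected


class TestSummarize:
    def test_hand_computable(self):
        cohort = gen_scale_cohort("feedback", n_subjects=2, seed=0)
        df = cohort.scores.copy()
        df.loc[df.test_index == 1, "phq9"] = [5.0, 7.0]
        summ = S.summarize(type(cohort)(df), "phq9", 1)
        assert summ.loc["feedback", "mean"] == pytest.approx(6.0)
        assert summ.loc["feedback", "sd"] == pytest.approx(np.sqrt(2.0))

    def test_matches_loop_oracle(self):
        cohort = gen_scale_cohort("depression_control", seed=1)
        summ = S.summarize(cohort, "sds", 3)
        vals = cohort.group_scores("depression_control", "sds", 3)
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert summ.loc["depression_control", "mean"] == pytest.approx(mean, abs=1e-12)
        assert summ.loc["depression_control", "sd"] == pytest.approx(sd, abs=1e-12)


class TestTTest:
    def test_identical_stats(self):
        res = S.t_test_from_stats(5.0, 1.0, 4, 5.0, 1.0, 4)
        assert res.t_stat == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_hand_computable_pooled(self):
        res = S.t_test_from_stats(10.0, 1.0, 4, 0.0, 1.0, 4, method="pooled")
        assert res.t_stat == pytest.approx(14.142, abs=1e-3)
        assert res.df == 6

    def test_strong_separation_significant(self):
        """Group summaries like a depressed-vs-normal baseline row give
        p < 0.001 under both pooled and Welch tests."""
        for method in ("pooled", "welch"):
            res = S.t_test_from_stats(31.40, 5.10, 4, 2.74, 3.19, 4, method=method)
            assert res.p_two_sided < 0.001

    @pytest.mark.parametrize("method", ["pooled", "welch"])
    def test_agrees_with_reference_implementation(self, method, rng):
        """Randomized grid vs scipy's summary-statistics t-test to 1e-10."""
        for _ in range(50):
            m1, m2 = rng.normal(size=2) * 10
            s1, s2 = rng.uniform(0.5, 5, size=2)
            n1, n2 = rng.integers(2, 30, size=2)
            res = S.t_test_from_stats(m1, s1, n1, m2, s2, n2, method=method)
            ref = sps.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=(method == "pooled")
            )
            assert res.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_unequal_means(self):
        with pytest.raises(ValueError):
            S.t_test_from_stats(1.0, 0.0, 4, 2.0, 0.0, 4)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            S.t_test_from_stats(1.0, 1.0, 1, 2.0, 1.0, 4)


class TestNullCalibration:
    def test_type_i_error_rate(self):
        """Pooled t-test on two same-distribution groups rejects at the 0.05
        level in 5% +/- 2% of 2000 seeded draws."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_draws = 2000
        for _ in range(n_draws):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            res = S.t_test_from_stats(
                a.mean(), a.std(ddof=1), 8, b.mean(), b.std(ddof=1), 8
            )
            rejections += res.p_two_sided < 0.05
        rate = rejections / n_draws
        assert 0.03 <= rate <= 0.07


class TestLongitudinalReport:
    def test_generator_consistency(self):
        """Default study cohort: feedback means decline on all scales while
        control trends are flat-ish, and late-test feedback-vs-depression
        p-values are small."""
        cohort = gen_study_cohort(seed=3)
        rep = S.longitudinal_report(cohort)
        trends = rep.attrs["trends"]
        for scale in S.SCALES:
            assert trends[(scale, "feedback")] == -1
            p_last = rep.loc[(scale, 6), "p_feedback_vs_depression_control"]
            p_first = rep.loc[(scale, 1), "p_feedback_vs_depression_control"]
            assert p_last < 0.01
            assert p_last < p_first

    def test_null_cohort_mostly_insignificant(self):
        """Feedback drawn flat (trend 0) behaves like the depression control:
        |t| small at most tests across seeds."""
        insig = 0
        total = 0
        for seed in range(5):
            from eegmusic.synth import ScaleCohort

            fb = gen_scale_cohort("feedback", trend=0.0, seed=seed)
            dc = gen_scale_cohort("depression_control", seed=100 + seed)
            nc = gen_scale_cohort("normal_control", seed=200 + seed)
            rep = S.longitudinal_report(ScaleCohort.combine(fb, dc, nc))
            ps = rep["p_feedback_vs_depression_control"]
            insig += (ps > 0.05).sum()
            total += len(ps)
        assert insig / total >= 0.9

    def test_missing_group_rejected(self):
        cohort = gen_scale_cohort("feedback", seed=0)
        with pytest.raises(ValueError, match="missing groups"):
            S.longitudinal_report(cohort)
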