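import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

from fallstack.evaluation import (
    ROCResult,
    compare_models,
    compute_roc,
    false_alarms_per_day,
    optimal_point,
    run_external,
    run_losocv,
    sensitivity_threshold,
    summarize_subjects,
)

from .oracles import naive_auc, naive_optimal_point, naive_ranksum_exact_p


class TestComputeRoc:
    def test_perfect_ranking_gives_auc_one(self):
        roc = compute_roc([0, 0, 1, 1], [1, 2, 3, 4], n_bootstrap=0)
        assert roc.auc == 1.0

    def test_interleaved_ranking_gives_auc_three_quarters(self):
        roc = compute_roc([0, 1, 0, 1], [1, 2, 3, 4], n_bootstrap=0)
        assert roc.auc == naive_auc([0, 1, 0, 1], [1, 2, 3, 4]) == 0.75

    @pytest.mark.parametrize("n,seed", [(50, 0), (200, 1), (500, 2)])
    def test_auc_equals_pairwise_probability(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        # quantize to force ties, exercising the ties-count-half rule
        scores = np.round(rng.normal(0, 1, n) + labels, 1)
        roc = compute_roc(labels, scores, n_bootstrap=0)
        assert roc.auc == pytest.approx(naive_auc(labels, scores), abs=1e-12)

    def test_random_scores_near_chance_with_ci(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.normal(0, 1, 200)
        roc = compute_roc(labels, scores, n_bootstrap=300, seed=3)
        assert roc.ci_low < 0.5 < roc.ci_high
        assert abs(roc.auc - 0.5) < 0.15

    def test_sensitivity_monotone_as_threshold_falls(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        roc = compute_roc(labels, rng.normal(0, 1, 100), n_bootstrap=0)
        assert np.all(np.diff(roc.sensitivity) >= 0)  # thresholds descend
        assert 0.0 <= roc.auc <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_roc([1, 1, 1], [1, 2, 3], n_bootstrap=0)


class TestOptimalPoint:
    def test_perfect_classifier_hits_sens_and_spec_one(self):
        roc = compute_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], n_bootstrap=0)
        _, sens, spec = optimal_point(roc)
        assert (sens, spec) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = np.round(rng.normal(0, 1, 30), 1)
        roc = compute_roc(labels, scores, n_bootstrap=0)
        thr, sens, spec = optimal_point(roc)
        o_thr, o_sens, o_spec = naive_optimal_point(list(labels), list(scores))
        assert sens + spec == pytest.approx(o_sens + o_spec, abs=1e-12)
        assert (sens, spec) == pytest.approx((o_sens, o_spec), abs=1e-12)

    def test_constant_scores_tie_break_to_lower_threshold(self):
        roc = compute_roc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5], n_bootstrap=0)
        thr, sens, spec = optimal_point(roc)
        assert sens + spec == pytest.approx(1.0)
        assert sens == 1.0  # lower threshold preferred -> alarm on everything

    def test_empty_roc_rejected(self):
        empty = ROCResult(np.array([]), np.array([]), np.array([]), 0.5)
        with pytest.raises(ValueError):
            optimal_point(empty)


class TestLosocv:
    def test_folds_partition_subjects(self, lab_features, synthetic_feature_table):
        res = run_losocv(synthetic_feature_table, "threshold")
        subjects = sorted(synthetic_feature_table["subject"].unique())
        assert sorted(res["per_subject"]) == subjects
        assert len(res["scores"]) == len(synthetic_feature_table)
        counts = res["scores"].groupby("subject").size()
        for s in subjects:
            assert counts[s] == (synthetic_feature_table["subject"] == s).sum()

    def test_subject_order_invariance(self, synthetic_feature_table):
        shuffled = synthetic_feature_table.sample(
            frac=1.0, random_state=3
        ).reset_index(drop=True)
        a = run_losocv(synthetic_feature_table, "threshold")
        b = run_losocv(shuffled, "threshold")
        assert a["per_subject"] == b["per_subject"]

    def test_single_class_fold_flagged_and_excluded(self, synthetic_feature_table):
        df = synthetic_feature_table.copy()
        df.loc[df["subject"] == "S00", "is_fall"] = True
        res = run_losocv(df, "threshold")
        assert res["per_subject"]["S00"]["excluded"]
        assert res["summary"]["n_subjects"] == 7

    def test_requires_two_subjects(self, synthetic_feature_table):
        one = synthetic_feature_table[synthetic_feature_table["subject"] == "S00"]
        with pytest.raises(ValueError, match="2 subjects"):
            run_losocv(one, "threshold")

    def test_external_rejects_subject_overlap(self, synthetic_feature_table):
        with pytest.raises(ValueError, match="overlap"):
            run_external(synthetic_feature_table, synthetic_feature_table,
                         "threshold")

    def test_location_filter_restricts_test_clips_only(
        self, synthetic_feature_table
    ):
        df = synthetic_feature_table.copy()
        df["location"] = np.where(df["clip_id"] % 2 == 0, "pocket", "hand")
        res = run_losocv(df, "threshold", test_location="pocket")
        n_pocket = int((df["location"] == "pocket").sum())
        assert len(res["scores"]) == n_pocket
        ext = run_external(
            df[df["subject"] < "S04"], df[df["subject"] >= "S04"],
            "threshold", test_location="hand",
        )
        assert len(ext["scores"]) == int(
            ((df["subject"] >= "S04") & (df["location"] == "hand")).sum()
        )

    def test_summary_reports_mean_and_196_sem(self):
        per = {
            "A": {"auc": 0.9, "sensitivity": 0.8, "specificity": 0.7},
            "B": {"auc": 1.0, "sensitivity": 0.9, "specificity": 0.8},
        }
        s = summarize_subjects(per)
        assert s["auc_mean"] == pytest.approx(0.95)
        sem = np.std([0.9, 1.0], ddof=1) / np.sqrt(2)
        assert s["auc_ci95"] == pytest.approx(1.96 * sem)


class TestFalseAlarms:
    def _tables(self, home_scores, fall_scores):
        import pandas as pd

        from fallstack.features import FEATURE_NAMES, META_COLUMNS

        def table(scores, is_fall):
            df = pd.DataFrame(
                {
                    "clip_id": range(len(scores)),
                    "subject": "H",
                    "population": "amputee",
                    "location": "pocket",
                    "is_fall": is_fall,
                }
            )
            feats = pd.DataFrame(
                np.zeros((len(scores), 40)), columns=list(FEATURE_NAMES)
            )
            feats["accel.resultant.max"] = scores
            return pd.concat([df, feats], axis=1)

        return table(home_scores, False), table(fall_scores, True)

    def test_rate_arithmetic(self):
        from fallstack.detector import ThresholdModel

        home, falls = self._tables(
            home_scores=[5.0] * 10 + [1.0] * 30, fall_scores=[4.0] * 10
        )
        out = false_alarms_per_day(ThresholdModel(), home, falls,
                                   target_sensitivity=0.9, home_days=2.0)
        assert out["n_alarms"] == 10
        assert out["rate_per_day"] == 5.0

    def test_zero_target_sensitivity_never_alarms(self):
        from fallstack.detector import ThresholdModel

        home, falls = self._tables([5.0] * 10, [4.0] * 10)
        out = false_alarms_per_day(ThresholdModel(), home, falls,
                                   target_sensitivity=0.0, home_days=2.0)
        assert out["rate_per_day"] == 0.0

    def test_threshold_is_largest_achieving_target(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        assert sensitivity_threshold(scores, 0.9) == 2.0
        assert sensitivity_threshold(scores, 1.0) == 1.0
        assert sensitivity_threshold(scores, 0.05) == 10.0

    def test_home_stream_with_falls_rejected(self):
        from fallstack.detector import ThresholdModel

        home, falls = self._tables([5.0], [4.0])
        with pytest.raises(ValueError, match="fall-free"):
            false_alarms_per_day(ThresholdModel(), falls, falls, 0.9, 1.0)


class TestCompareModels:
    def test_identical_groups_exact_p_is_one(self):
        out = compare_models([0.9, 0.95, 1.0], [0.9, 0.95, 1.0])
        assert out["method"] == "exact"
        assert out["p_value"] == 1.0

    def test_disjoint_groups_match_enumeration_oracle(self):
        out = compare_models([1, 2, 3], [4, 5, 6])
        assert out["p_value"] == pytest.approx(
            naive_ranksum_exact_p([1, 2, 3], [4, 5, 6])
        )
        assert out["p_value"] == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_p_matches_oracle_on_random_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = list(np.round(rng.normal(0, 1, 5), 1))
        b = list(np.round(rng.normal(0.5, 1, 5), 1))
        out = compare_models(a, b)
        assert out["method"] == "exact"
        assert out["p_value"] == pytest.approx(naive_ranksum_exact_p(a, b))

    def test_normal_approximation_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 10)
        out = compare_models(a, b)
        ref = ranksums(a, b)
        assert out["method"] == "normal"
        assert out["statistic"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(21)
        powers = []
        for shift in (0.2, 0.8, 1.6):
            rejections = 0
            for _ in range(500):
                a = rng.normal(0, 1, 10)
                b = rng.normal(shift, 1, 10)
                if compare_models(a, b)["p_value"] < 0.05:
                    rejections += 1
            powers.append(rejections / 500)
        assert powers[0] < powers[1] < powers[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_models([], [1.0])

    def test_degenerate_pooled_sample(self):
        out = compare_models([1.0, 1.0], [1.0, 1.0, 1.0])
        assert out["p_value"] == 1.0


class TestPlottingHook:
    def test_roc_curve_figure_written(self, tmp_path):
        roc = compute_roc([0, 1, 0, 1, 1], [0.1, 0.9, 0.4, 0.7, 0.8],
                          n_bootstrap=50, seed=0)
        from fallstack.evaluation import plot_roc

        out = tmp_path / "roc.png"
        plot_roc({"stacked": roc}, out)
        assert out.stat().st_size > 0


_scores = st.lists(
    st.integers(min_value=-5, max_value=5).map(float), min_size=2, max_size=12
)


class TestStatisticalProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=_scores, b=_scores)
    def test_ranksum_p_valid_and_symmetric(self, a, b):
        out_ab = compare_models(a, b)
        out_ba = compare_models(b, a)
        assert 0.0 <= out_ab["p_value"] <= 1.0
        assert out_ab["p_value"] == pytest.approx(out_ba["p_value"], abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        pos=st.lists(st.integers(-10, 10).map(float), min_size=1, max_size=15),
        neg=st.lists(st.integers(-10, 10).map(float), min_size=1, max_size=15),
    )
    def test_auc_always_matches_pairwise_oracle(self, pos, neg):
        labels = [1] * len(pos) + [0] * len(neg)
        scores = pos + neg
        roc = compute_roc(labels, scores, n_bootstrap=0)
        assert roc.auc == pytest.approx(naive_auc(labels, scores), abs=1e-12)
        # a monotone transform of the scores never changes the AUC
        warped = [s**3 + 2 * s for s in scores]
        assert compute_roc(labels, warped, n_bootstrap=0).auc == \
            pytest.approx(roc.auc, abs=1e-12)
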