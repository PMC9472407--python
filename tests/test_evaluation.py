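import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsport._util import ValidationError
from prsport.evaluation import (
    HIGH_GROUP, MID_GROUP, build_evaluation_report, classify_aggressive,
    covariate_adjusted_auc, covariate_adjusted_or, delong_test,
    fill_missing_ages, percentile_groups, roc_auc,
)


class TestClassifyAggressive:
    def test_t4_stage(self):
        assert classify_aggressive("T4", 6.0, "stage") is True

    def test_t2_gleason7_not_aggressive(self):
        assert classify_aggressive("T2", 7.0, "gleason") is False

    def test_missing_stage_not_evaluable(self):
        assert classify_aggressive(None, 9.0, "gleason") is True
        assert classify_aggressive(None, 9.0, "stage") is None

    def test_gleason_boundary(self):
        assert classify_aggressive("T1", 8.0, "gleason") is True
        assert classify_aggressive("T1", 7.0, "gleason") is False

    def test_unknown_codes_rejected(self):
        with pytest.raises(ValidationError):
            classify_aggressive("T5", 6.0, "stage")
        with pytest.raises(ValidationError):
            classify_aggressive("T1", 11.0, "gleason")
        with pytest.raises(ValidationError):
            classify_aggressive("T1", 6.0, "both")


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.concatenate([np.linspace(1.1, 2, 50), np.linspace(0, 0.9, 50)])
        labels = np.repeat([True, False], 50)
        assert roc_auc(scores, labels).auc == 1.0

    def test_chance_level_large_n(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(20_000)
        labels = np.repeat([True, False], 10_000)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.01

    def test_tie_counting_oracle(self):
        # cases {2,3}, controls {1,2}: pairwise wins (1 + 0.5 + 1 + 1)/4
        res = roc_auc([2.0, 3.0, 1.0, 2.0], [True, True, False, False])
        assert res.auc == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [True, True])

    def test_complement_identity(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.concatenate([np.ones(20, bool), rng.random(40) < 0.5])
        if labels.all() or not labels.any():
            return
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores * 2) + 5, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_contains_auc_both_scales(self, rng):
        scores = rng.normal(size=300) + np.repeat([0.5, 0.0], 150)
        labels = np.repeat([True, False], 150)
        for scale in ("auc", "logit"):
            res = roc_auc(scores, labels, ci_scale=scale)
            assert res.ci_low <= res.auc <= res.ci_high


class TestDelong:
    def test_self_comparison_zero(self, rng):
        scores = rng.normal(size=100)
        labels = np.repeat([True, False], 50)
        r = roc_auc(scores, labels)
        out = delong_test(r, r, paired=True)
        assert out["z"] == 0.0
        assert out["p_value"] == 1.0

    def test_unpaired_equal_aucs(self, rng):
        scores = rng.normal(size=80)
        labels = np.repeat([True, False], 40)
        r1 = roc_auc(scores, labels)
        r2 = roc_auc(scores.copy(), labels)
        out = delong_test(r1, r2, paired=False)
        assert out["z"] == 0.0

    def test_paired_requires_matching_counts(self, rng):
        r1 = roc_auc(rng.normal(size=40), np.repeat([True, False], 20))
        r2 = roc_auc(rng.normal(size=60), np.repeat([True, False], 30))
        with pytest.raises(ValidationError):
            delong_test(r1, r2, paired=True)

    def test_variance_matches_bootstrap_oracle(self):
        # fixed 200-sample fixture; stratified bootstrap of the AUC
        rng = np.random.default_rng(2024)
        cases = rng.normal(0.8, 1.0, 100)
        ctrls = rng.normal(0.0, 1.0, 100)
        scores = np.concatenate([cases, ctrls])
        labels = np.repeat([True, False], 100)
        res = roc_auc(scores, labels)
        n_boot = 10_000
        aucs = np.empty(n_boot)
        from scipy.stats import rankdata
        for i in range(n_boot):
            c = cases[rng.integers(0, 100, 100)]
            k = ctrls[rng.integers(0, 100, 100)]
            ranks = rankdata(np.concatenate([c, k]))
            aucs[i] = (ranks[:100].sum() - 100 * 101 / 2) / (100 * 100)
        boot_var = aucs.var(ddof=1)
        assert res.variance == pytest.approx(boot_var, rel=0.10)

    def test_detects_real_difference(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([True, False], 1000)
        strong = np.concatenate([rng.normal(1, 1, 1000), rng.normal(0, 1, 1000)])
        weak = np.concatenate([rng.normal(0.1, 1, 1000), rng.normal(0, 1, 1000)])
        out = delong_test(roc_auc(strong, labels), roc_auc(weak, labels),
                          paired=False)
        assert out["p_value"] < 1e-10


class TestPercentileGroups:
    def test_counts_for_100_distinct(self, rng):
        scores = rng.permutation(100).astype(float)
        labels = percentile_groups(scores)
        assert np.sum(labels == HIGH_GROUP) == 10
        assert np.sum(labels == MID_GROUP) == 21

    def test_all_identical_rejected(self):
        with pytest.raises(ValidationError):
            percentile_groups(np.ones(50))

    def test_monotone_invariance(self, rng):
        scores = rng.normal(size=80)
        a = percentile_groups(scores)
        b = percentile_groups(np.tanh(scores) * 10)
        np.testing.assert_array_equal(a, b)


class TestCovariateAdjustedOr:
    def test_cross_product_2x2(self):
        # high: 30 cases / 10 controls; mid: 20 cases / 20 controls
        groups = np.array([HIGH_GROUP] * 40 + [MID_GROUP] * 40, dtype=object)
        status = np.array([True] * 30 + [False] * 10 + [True] * 20 + [False] * 20)
        res = covariate_adjusted_or(groups, status)
        assert res.odds_ratio == pytest.approx(3.0, rel=1e-6)
        assert res.ci_low < 3.0 < res.ci_high

    def test_independent_groups_or_near_one(self, rng):
        n = 4000
        scores = rng.normal(size=n)
        status = rng.random(n) < 0.5
        groups = percentile_groups(scores)
        res = covariate_adjusted_or(groups, status)
        assert 0.8 < res.odds_ratio < 1.25

    def test_empty_cell_rejected(self):
        groups = np.array([HIGH_GROUP] * 10 + [MID_GROUP] * 10, dtype=object)
        status = np.array([True] * 10 + [False] * 10)
        with pytest.raises(ValidationError, match="exact"):
            covariate_adjusted_or(groups, status)

    def test_age_median_fill_used(self, rng):
        n = 400
        scores = rng.normal(size=n)
        status = rng.random(n) < 0.5
        if status.all() or not status.any():
            status[:2] = [True, False]
        groups = percentile_groups(scores)
        ages = rng.uniform(40, 90, n)
        ages[::7] = np.nan
        cov = pd.DataFrame({"age": ages})
        res = covariate_adjusted_or(groups, status, cov)
        assert res.covariates == ["age"]
        assert np.isfinite(res.odds_ratio)

    def test_ci_coverage_500_replicates(self):
        # generative OR = 2 for high vs mid; Wald CI coverage ~ 95%
        rng = np.random.default_rng(11)
        true_or = 2.0
        covered = 0
        n_reps = 500
        for _ in range(n_reps):
            scores = rng.normal(size=600)
            groups = percentile_groups(scores)
            high = groups == HIGH_GROUP
            logit = -0.2 + np.log(true_or) * high.astype(float)
            status = rng.random(600) < 1 / (1 + np.exp(-logit))
            try:
                res = covariate_adjusted_or(groups, status)
            except ValidationError:
                continue
            if res.ci_low <= true_or <= res.ci_high:
                covered += 1
        rate = covered / n_reps
        half_width = 2.576 * np.sqrt(0.95 * 0.05 / n_reps)
        assert abs(rate - 0.95) < half_width + 0.01


class TestFillMissingAges:
    def test_median_fill(self):
        out = fill_missing_ages([60.0, np.nan, 80.0, 70.0])
        assert out[1] == 70.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            fill_missing_ages([np.nan, np.nan])


class TestCovariateAdjustedAuc:
    def test_constant_covariates_match_prs_only(self, rng):
        n = 500
        scores = rng.normal(size=n)
        labels = rng.random(n) < 1 / (1 + np.exp(-scores))
        cov = pd.DataFrame({"age": np.full(n, 60.0)})
        out = covariate_adjusted_auc(scores, labels, cov)
        assert out["model_auc"].auc == pytest.approx(out["prs_only_auc"].auc,
                                                     abs=1e-9)

    def test_age_driven_auc(self, rng):
        n = 3000
        scores = rng.normal(size=n)  # pure noise
        age = rng.uniform(40, 90, n)
        labels = rng.random(n) < 1 / (1 + np.exp(-(age - 65) / 8))
        out = covariate_adjusted_auc(scores, labels, pd.DataFrame({"age": age}))
        assert abs(out["prs_only_auc"].auc - 0.5) < 0.03
        assert out["model_auc"].auc > 0.6


class TestBuildReport:
    def _entries(self, rng, n=300):
        scores = rng.normal(size=n)
        status = rng.random(n) < 1 / (1 + np.exp(-scores))
        stage = np.where(status, np.where(rng.random(n) < 0.2, "T4", "T2"), None)
        gleason = np.where(status, np.where(rng.random(n) < 0.4, 9.0, 6.0), np.nan)
        meta = pd.DataFrame({"stage": stage, "gleason": gleason})
        return {
            "scores": {"EUR": scores, "AFR": rng.normal(size=n)},
            "status": status,
            "covariates": pd.DataFrame({"age": rng.uniform(40, 90, n)}),
            "metadata": meta,
        }

    def test_row_structure(self, rng):
        report = build_evaluation_report(
            {"c1": self._entries(rng), "c2": self._entries(rng)},
            classifiers=("stage", "gleason"),
        )
        assert len(report) == 2 * 2 * 3  # cohorts x ancestries x endpoints
        assert set(report["endpoint"]) == {
            "case_control", "aggressive_stage", "aggressive_gleason"
        }

    def test_empty_classifiers(self, rng):
        report = build_evaluation_report({"c1": self._entries(rng)},
                                         classifiers=())
        assert set(report["endpoint"]) == {"case_control"}

    def test_matched_weights_win(self):
        # scores aligned with the generating liability beat noise columns
        rng = np.random.default_rng(3)
        n = 2000
        g = rng.normal(size=n)
        status = rng.random(n) < 1 / (1 + np.exp(-1.5 * g))
        entry = {
            "scores": {"own": g, "other": 0.2 * g + rng.normal(size=n)},
            "status": status,
        }
        report = build_evaluation_report({"c": entry}, classifiers=())
        by_anc = report.set_index("ancestry")["auc"]
        assert by_anc["own"] > by_anc["other"]

    def test_failed_row_flagged_not_fatal(self, rng):
        entry = self._entries(rng, n=100)
        entry["scores"]["bad"] = np.ones(100)  # degenerate
        report = build_evaluation_report({"c": entry}, classifiers=())
        bad = report[report["ancestry"] == "bad"]
        assert not bad["ok"].iloc[0]
        assert report[report["ancestry"] == "EUR"]["ok"].iloc[0]
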