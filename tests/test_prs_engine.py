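import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_proxy_map
from prsport._util import ValidationError
from prsport.io_formats import ProxyMap, ScoreDefinition
from prsport.prs_engine import (
    adjust_weight, compute_raw_prs, impute_missing_doses, resolve_for_datasets,
    resolve_variants, score_cohort, standardize_scores,
)


def make_score(n, prefix="rs", or_value=1.1, ancestries=("EUR",)):
    variants = pd.DataFrame({
        "variant_id": [f"{prefix}{i}" for i in range(n)],
        "chrom": "1",
        "pos": 1000 + 10 * np.arange(n),
        "effect_allele": "A",
        "other_allele": "G",
    })
    return ScoreDefinition(
        score_name="fixture", variants=variants,
        log_weights={a: np.full(n, np.log(or_value)) for a in ancestries},
    )


class TestAdjustWeight:
    def test_ln2(self):
        assert adjust_weight(2.0, 1.0) == pytest.approx(0.693147, abs=1e-6)

    def test_null_or(self):
        assert adjust_weight(1.0, 0.73) == 0.0

    def test_half_r2(self):
        assert adjust_weight(1.5, 0.5) == pytest.approx(0.202733, abs=1e-6)

    @pytest.mark.parametrize("bad_or", [0.0, -1.0])
    def test_nonpositive_or(self, bad_or):
        with pytest.raises(ValidationError):
            adjust_weight(bad_or, 0.5)


class TestResolveVariants:
    def test_direct_genotyped(self, small_score):
        resolved = resolve_variants(
            small_score, {"rs0", "rs1", "rs2", "rs3", "rs4"}, ProxyMap()
        )
        assert resolved.n_markers == 5
        assert (resolved.used["r2"] == 1.0).all()
        np.testing.assert_allclose(
            resolved.betas("EUR"), small_score.log_weights["EUR"]
        )

    def test_below_threshold_proxy_dropped(self, small_score):
        pmap = build_proxy_map([("rs0", "px0", 0.3, True, "proxy", np.nan)])
        resolved = resolve_variants(
            small_score, {"px0", "rs1", "rs2", "rs3", "rs4"}, pmap
        )
        assert resolved.n_markers == 4
        assert resolved.dropped.iloc[0]["source_id"] == "rs0"
        assert "lacked proxy" in resolved.dropped.iloc[0]["reason"]

    def test_proxy_weight_adjusted(self, small_score):
        pmap = build_proxy_map([("rs0", "px0", 0.8, True, "proxy", np.nan)])
        resolved = resolve_variants(
            small_score, {"px0", "rs1", "rs2", "rs3", "rs4"}, pmap
        )
        row = resolved.used[resolved.used["source_id"] == "rs0"].iloc[0]
        assert row["used_id"] == "px0"
        assert row["beta_EUR"] == pytest.approx(np.log(1.2) * 0.8)

    def test_opposite_direction_proxy_flips_sign(self, small_score):
        pmap = build_proxy_map([("rs0", "px0", 0.9, False, "proxy", np.nan)])
        resolved = resolve_variants(
            small_score, {"px0", "rs1", "rs2", "rs3", "rs4"}, pmap
        )
        row = resolved.used[resolved.used["source_id"] == "rs0"].iloc[0]
        assert row["beta_EUR"] == pytest.approx(-np.log(1.2) * 0.9)

    def test_tie_break_lexicographic(self, small_score):
        pmap = build_proxy_map([
            ("rs0", "pxB", 0.8, True, "proxy", np.nan),
            ("rs0", "pxA", 0.8, True, "proxy", np.nan),
        ])
        resolved = resolve_variants(
            small_score, {"pxA", "pxB", "rs1", "rs2", "rs3", "rs4"}, pmap
        )
        row = resolved.used[resolved.used["source_id"] == "rs0"].iloc[0]
        assert row["used_id"] == "pxA"

    def test_dictionary_absent_drop_147_to_146(self):
        # 147 variants, one flagged absent from the variant dictionary
        score = make_score(147)
        genotyped = {f"rs{i}" for i in range(147)}
        dictionary = genotyped - {"rs33"}
        resolved = resolve_variants(score, genotyped, ProxyMap(),
                                    variant_dictionary=dictionary)
        assert resolved.n_markers == 146
        assert resolved.dropped.iloc[0]["reason"] == "unmatched"

    def test_two_marker_expansion_269_to_270(self):
        score = make_score(269)
        pmap = build_proxy_map([
            ("rs100", "mkA", 1.0, True, "expand", 0.30),
            ("rs100", "mkB", 1.0, True, "expand", 0.10),
        ])
        genotyped = {f"rs{i}" for i in range(269)} | {"mkA", "mkB"}
        resolved = resolve_variants(score, genotyped, pmap)
        assert resolved.n_markers == 270
        assert resolved.expansions == [("rs100", ("mkA", "mkB"))]
        betas = resolved.used.set_index("used_id")["beta_EUR"]
        assert betas["mkA"] == pytest.approx(0.30)
        assert betas["mkB"] == pytest.approx(0.10)
        assert "rs100" not in set(resolved.used["used_id"])

    def test_every_source_accounted_once(self, small_score):
        pmap = build_proxy_map([("rs0", "px0", 0.5, True, "proxy", np.nan)])
        resolved = resolve_variants(small_score, {"px0", "rs1", "rs2"}, pmap)
        sources = (set(resolved.used["source_id"])
                   | set(resolved.dropped["source_id"]))
        assert sources == set(small_score.variants["variant_id"])

    def test_shared_mode_uses_intersection(self, small_score):
        sets = {"d1": {"rs0", "rs1", "rs2", "rs3", "rs4"},
                "d2": {"rs0", "rs1", "rs2"}}
        out = resolve_for_datasets(small_score, sets, ProxyMap(), mode="shared")
        assert out["d1"].n_markers == out["d2"].n_markers == 3
        opt = resolve_for_datasets(small_score, sets, ProxyMap(), mode="optimal")
        assert opt["d1"].n_markers == 5

    def test_bad_threshold(self, small_score):
        with pytest.raises(ValidationError):
            resolve_variants(small_score, set(), ProxyMap(), r2_threshold=0.0)


class TestImputation:
    def test_site_mean_fill(self):
        d = np.array([[0.0], [1.0], [2.0], [np.nan]])
        filled, counts, bad = impute_missing_doses(d, ["A", "A", "A", "A"])
        assert filled[3, 0] == pytest.approx(1.0)
        assert counts.tolist() == [0, 0, 0, 1]
        assert bad == []

    def test_site_mean_not_pooled(self):
        d = np.array([[0.0], [np.nan], [2.0], [2.0]])
        filled, _, _ = impute_missing_doses(d, ["A", "A", "B", "B"])
        assert filled[1, 0] == pytest.approx(0.0)

    def test_no_missing_unchanged(self, rng):
        d = rng.integers(0, 3, (10, 4)).astype(float)
        filled, counts, bad = impute_missing_doses(d, np.zeros(10))
        np.testing.assert_array_equal(filled, d)
        assert counts.sum() == 0

    def test_fallback_to_cohort_mean(self):
        d = np.array([[np.nan], [np.nan], [2.0], [0.0]])
        filled, _, _ = impute_missing_doses(d, ["A", "A", "B", "B"])
        np.testing.assert_allclose(filled[:2, 0], 1.0)

    def test_all_missing_variant_flagged(self):
        d = np.array([[np.nan, 1.0], [np.nan, 0.0]])
        filled, _, bad = impute_missing_doses(d, ["A", "B"])
        assert bad == [0]
        assert np.isnan(filled[:, 0]).all()


class TestScoring:
    def test_hand_sum(self):
        assert compute_raw_prs(np.array([[2.0, 1.0]]),
                               np.array([0.5, -0.2]))[0] == pytest.approx(0.8)

    def test_zero_weights(self, rng):
        d = rng.integers(0, 3, (7, 3)).astype(float)
        np.testing.assert_array_equal(compute_raw_prs(d, np.zeros(3)),
                                      np.zeros(7))

    def test_3x3_brute_force(self, rng):
        d = rng.integers(0, 3, (3, 3)).astype(float)
        w = rng.normal(size=3)
        expected = [sum(d[i, j] * w[j] for j in range(3)) for i in range(3)]
        np.testing.assert_allclose(compute_raw_prs(d, w), expected)

    def test_missing_rejected(self):
        with pytest.raises(ValidationError):
            compute_raw_prs(np.array([[np.nan]]), np.array([1.0]))

    def test_permutation_invariance(self, rng):
        d = rng.integers(0, 3, (20, 6)).astype(float)
        w = rng.normal(size=6)
        base = compute_raw_prs(d, w)
        perm_s = rng.permutation(20)
        np.testing.assert_allclose(compute_raw_prs(d[perm_s], w), base[perm_s])
        perm_v = rng.permutation(6)
        np.testing.assert_allclose(compute_raw_prs(d[:, perm_v], w[perm_v]),
                                   base, rtol=1e-12)

    def test_monotonicity(self, rng):
        d = rng.integers(0, 2, (5, 4)).astype(float)
        w = np.abs(rng.normal(size=4))
        before = compute_raw_prs(d, w)
        d2 = d.copy()
        d2[2, 1] += 1
        after = compute_raw_prs(d2, w)
        assert after[2] >= before[2]
        np.testing.assert_allclose(np.delete(after, 2), np.delete(before, 2))


class TestStandardize:
    def test_triple(self):
        np.testing.assert_allclose(standardize_scores([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0])

    def test_location_invariance(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(standardize_scores(x),
                                   standardize_scores(x + 100.0), atol=1e-9)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60).filter(
        lambda v: np.std(v) > 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_unit_sd_property(self, values):
        z = standardize_scores(values)
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            standardize_scores([2.0, 2.0, 2.0])


class TestScoreCohort:
    def test_end_to_end(self, tiny_cohort, small_score):
        sub = small_score.variants.iloc[:3].copy()
        sub["variant_id"] = ["v1", "v2", "v3"]
        score = ScoreDefinition(
            score_name="tiny", variants=sub,
            log_weights={a: w[:3] for a, w in small_score.log_weights.items()},
        )
        resolved = resolve_variants(score, {"v1", "v2", "v3"}, ProxyMap())
        table = score_cohort(tiny_cohort, resolved, "EUR")
        assert table["n_filled"].tolist() == [0, 1, 0, 0]
        assert table["standardized"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["standardized"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        # mean-fill neutrality: s2's missing v2 dose becomes site X's mean (1.0)
        w = score.log_weights["EUR"]
        expected_raw_s2 = 1.0 * w[0] + 1.0 * w[1] + 0.0 * w[2]
        assert table["raw"].iloc[1] == pytest.approx(expected_raw_s2)

    def test_r2_one_proxy_equals_direct(self, tiny_cohort, small_score):
        sub = small_score.variants.iloc[:3].copy()
        sub["variant_id"] = ["w1", "v2", "v3"]  # w1 ungenotyped, proxied by v1
        score = ScoreDefinition(
            score_name="tiny", variants=sub,
            log_weights={a: w[:3] for a, w in small_score.log_weights.items()},
        )
        pmap = build_proxy_map([("w1", "v1", 1.0, True, "proxy", np.nan)])
        via_proxy = resolve_variants(score, {"v1", "v2", "v3"}, pmap)
        direct_sub = sub.copy()
        direct_sub["variant_id"] = ["v1", "v2", "v3"]
        direct_score = ScoreDefinition(
            score_name="tiny", variants=direct_sub,
            log_weights={a: w[:3] for a, w in small_score.log_weights.items()},
        )
        direct = resolve_variants(direct_score, {"v1", "v2", "v3"}, ProxyMap())
        t1 = score_cohort(tiny_cohort, via_proxy, "AFR")
        t2 = score_cohort(tiny_cohort, direct, "AFR")
        np.testing.assert_allclose(t1["raw"], t2["raw"])

    def test_unknown_ancestry(self, tiny_cohort, small_score):
        sub = small_score.variants.iloc[:3].copy()
        sub["variant_id"] = ["v1", "v2", "v3"]
        score = ScoreDefinition(
            score_name="tiny", variants=sub,
            log_weights={"EUR": small_score.log_weights["EUR"][:3]},
        )
        resolved = resolve_variants(score, {"v1", "v2", "v3"}, ProxyMap())
        with pytest.raises(ValidationError, match="EUR"):
            score_cohort(tiny_cohort, resolved, "MARS")
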