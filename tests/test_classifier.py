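import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.classifier import (
    InsufficientDataError,
    UndefinedEffectError,
    auc_rank,
    classify_interactions,
    cohens_d,
    enrichment_factor,
    export_distribution_summary,
    mann_whitney,
    roc_curve,
    youden_threshold,
)
from .conftest import make_score_set


class TestRocCurve:
    @pytest.mark.parametrize(
        "binders, decoys, expected_auc",
        [
            ([-10, -9, -8], [-5, -4, -3], 1.0),   # perfect separation
            ([-5, -4, -3], [-5, -4, -3], 0.5),    # identical multisets
            ([-9, -7], [-8, -6], 0.75),           # 3 of 4 pairs correctly ordered
        ],
    )
    def test_auc_examples(self, binders, decoys, expected_auc):
        result = roc_curve(make_score_set(binders, decoys))
        assert result.auc == pytest.approx(expected_auc, abs=1e-15)

    def test_perfect_separation_threshold_is_gap_midpoint(self):
        result = roc_curve(make_score_set([-10, -9, -8], [-5, -4, -3]))
        thr, j = youden_threshold(result)
        assert j == pytest.approx(1.0)
        assert thr == pytest.approx(-6.5)
        assert result.optimal_threshold == pytest.approx(-6.5)

    def test_identical_distributions_give_zero_j(self):
        result = roc_curve(make_score_set([-5, -4, -3], [-5, -4, -3]))
        assert result.youden_j == pytest.approx(0.0)

    def test_tie_between_candidates_broken_toward_most_negative(self):
        # J = 0.5 at both -8.5 and -6.5; the stringent threshold wins
        result = roc_curve(make_score_set([-9, -7], [-8, -6]))
        assert result.youden_j == pytest.approx(0.5)
        assert result.optimal_threshold == pytest.approx(-8.5)

    def test_requires_two_scores_per_class(self):
        with pytest.raises(InsufficientDataError):
            roc_curve(make_score_set([-9], [-5, -4]))

    def test_sensitivity_specificity_bounds_and_sentinels(self):
        result = roc_curve(make_score_set([-9, -7, -6], [-8, -5, -4]))
        pts = result.roc_points
        assert ((pts["sensitivity"] >= 0) & (pts["sensitivity"] <= 1)).all()
        assert ((pts["specificity"] >= 0) & (pts["specificity"] <= 1)).all()
        assert np.isfinite(pts["threshold"]).all()
        assert pts["threshold"].iloc[0] < -9 and pts["threshold"].iloc[-1] > -4

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(make_score_set([-9, -7], [-8, -6]), criterion="f1")


class TestAucRank:
    def test_examples(self):
        assert auc_rank(make_score_set([-10, -9], [-5, -4])) == 1.0
        # one tied pair of two, the other correct: (1 + 0.5)/2
        assert auc_rank(make_score_set([-9, -5], [-5, -5])) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.integers(-12, -2), min_size=2, max_size=15),
        st.lists(st.integers(-12, -2), min_size=2, max_size=15),
    )
    def test_trapezoidal_auc_equals_pair_statistic(self, binders, decoys):
        """Oracle equivalence, including heavy ties from the integer grid."""
        s = make_score_set(binders, decoys)
        assert abs(roc_curve(s).auc - auc_rank(s)) <= 1e-12


class TestMannWhitney:
    def test_perfect_separation_gives_zero_u(self):
        u, p = mann_whitney(make_score_set([-9, -8], [-5, -4]))
        assert u == 0.0
        assert p == pytest.approx(1 / 3)  # exact two-sided, n1=n2=2

    def test_no_shift_gives_p_one(self):
        u, p = mann_whitney(make_score_set([-9, -5], [-9, -5]))
        assert p == pytest.approx(1.0)

    def test_u_consistent_with_auc_rank(self, rng):
        for _ in range(20):
            b = rng.normal(-8, 1, size=rng.integers(5, 25))
            d = rng.normal(-6, 1, size=rng.integers(5, 25))
            s = make_score_set(b, d)
            u, _ = mann_whitney(s)
            assert auc_rank(s) == pytest.approx(1 - u / (b.size * d.size), abs=1e-12)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(make_score_set([-5, -4], [-5, -4])) == pytest.approx(0.0)

    def test_hand_computed_pooled_sd_example(self):
        # means -7 and -4, pooled SD sqrt(2): d = -3/sqrt(2)
        d = cohens_d(make_score_set([-8, -6], [-5, -3]))
        assert d == pytest.approx(-3 / math.sqrt(2), abs=1e-12)

    def test_sign_negative_when_binders_score_lower(self, rng):
        b = rng.normal(-9, 1, 30)
        d = rng.normal(-6, 1, 30)
        assert cohens_d(make_score_set(b, d)) < 0

    def test_zero_pooled_sd_is_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d(make_score_set([-5, -5], [-4, -4]))


class TestEnrichmentFactor:
    def test_whole_list_gives_one(self, rng):
        for _ in range(10):
            s = make_score_set(rng.normal(-8, 1, 12), rng.normal(-6, 1, 20))
            assert enrichment_factor(s, 1.0) == pytest.approx(1.0)

    def test_worked_example_top_quarter(self):
        s = make_score_set([-10, -9], [-8, -7, -6, -5, -4, -3])
        assert enrichment_factor(s, 0.25) == pytest.approx(4.0)

    def test_binders_ranked_last_give_zero(self):
        s = make_score_set([-2, -1], [-8, -7, -6, -5])
        assert enrichment_factor(s, 0.25) == 0.0

    def test_fraction_out_of_range_rejected(self):
        s = make_score_set([-9, -8], [-5, -4])
        for f in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                enrichment_factor(s, f)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(-12, -2, allow_nan=False), min_size=2, max_size=20),
        st.lists(st.floats(-12, -2, allow_nan=False), min_size=2, max_size=20),
        st.floats(0.05, 1.0),
    )
    def test_ef_bounds(self, binders, decoys, fraction):
        s = make_score_set(binders, decoys)
        ef = enrichment_factor(s, fraction)
        n = len(binders) + len(decoys)
        assert 0 <= ef <= min(n / len(binders), 1 / fraction) + 1e-9


class TestClassification:
    def make_thresholds(self):
        return {"T1": roc_curve(make_score_set([-10, -9, -8], [-5, -4, -3], "T1"))}

    def interactions(self, rows):
        return pd.DataFrame(rows, columns=["compound_id", "target_id", "mean_score"])

    def test_below_threshold_is_probable_binder(self):
        out = classify_interactions(
            self.interactions([("c1", "T1", -9.0)]), self.make_thresholds()
        )
        assert out["classification"].iloc[0] == "probable_binder"

    def test_exactly_at_threshold_is_nonbinder(self):
        thr = self.make_thresholds()
        at = thr["T1"].optimal_threshold
        out = classify_interactions(self.interactions([("c1", "T1", at)]), thr)
        assert out["classification"].iloc[0] == "probable_nonbinder"

    def test_target_without_threshold_is_unclassified(self):
        out = classify_interactions(
            self.interactions([("c1", "T9", -9.0)]), self.make_thresholds()
        )
        assert out["classification"].iloc[0] == "unclassified"

    @given(st.floats(-12, -2), st.floats(0.01, 3))
    def test_decreasing_a_score_never_flips_binder_to_nonbinder(self, score, delta):
        thr = self.make_thresholds()
        before = classify_interactions(
            self.interactions([("c", "T1", score)]), thr
        )["classification"].iloc[0]
        after = classify_interactions(
            self.interactions([("c", "T1", score - delta)]), thr
        )["classification"].iloc[0]
        if before == "probable_binder":
            assert after == "probable_binder"


class TestDistributionExport:
    def test_facets_and_threshold_consistency(self):
        sets = [
            make_score_set([-9, -8, -7], [-5, -4, -3], f"T{i}") for i in range(9)
        ]
        thresholds = {s.target_id: roc_curve(s) for s in sets}
        long, summary = export_distribution_summary(sets, thresholds)
        assert long["target_id"].nunique() == 9
        assert set(summary["label"]) == {"binder", "decoy"}
        for tid, thr in thresholds.items():
            col = summary.loc[summary["target_id"] == tid, "optimal_threshold"]
            assert (col == youden_threshold(thr)[0]).all()

    def test_empty_decoy_class_warns_and_emits_binders_only(self):
        s = make_score_set([-9, -8], [])
        with pytest.warns(UserWarning, match="no decoy scores"):
            long, summary = export_distribution_summary([s])
        assert set(long["label"]) == {"binder"}
        assert len(summary) == 1
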