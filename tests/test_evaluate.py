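"""ROC analysis: sweep construction, AUC, cut-off selection, group summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from capclean import (
    confusion_at,
    group_summary,
    roc_curve,
    select_cutoff,
    simulate_score_cohort,
)

FOUR_CASES = ([4.0, 3.5, 3.0, 2.5], [True, True, False, False])


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve(*FOUR_CASES)
        assert roc.auc == pytest.approx(1.0)

    def test_identical_scores_give_auc_half(self):
        roc = roc_curve([3.0, 3.0, 3.0, 3.0], [True, True, False, False])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="adequate"):
            roc_curve([1.0, 2.0], [True, True])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_equals_normalised_mann_whitney_u(self, seed):
        """Trapezoid AUC == U/(n+ * n-), including ties (scipy oracle)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.uniform(1, 5, n), 1)  # rounding forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or (~labels).all():
            labels[0] = ~labels[0]
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        auc = roc_curve(scores, labels).auc
        assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()))
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(1, 5, 30)
        labels = rng.random(30) < 0.6
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(scores) + 7, labels).auc
        assert a1 == pytest.approx(a2)


class TestSelectCutoff:
    def test_midpoint_convention_on_hand_enumerated_roc(self):
        """Adequate {4.0, 3.5} vs inadequate {3.0, 2.5}: cutoff is 3.25."""
        roc = select_cutoff(roc_curve(*FOUR_CASES), method="youden")
        assert roc.selected_cutoff == pytest.approx(3.25)
        assert roc.cutoff_sensitivity == pytest.approx(1.0)
        assert roc.cutoff_specificity == pytest.approx(1.0)

    def test_min_distance_agrees_on_separable_data(self):
        roc = select_cutoff(roc_curve(*FOUR_CASES), method="min_distance")
        assert roc.selected_cutoff == pytest.approx(3.25)

    def test_cutoff_between_group_extremes_when_separable(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(4.0, 4.8, 20)
        neg = rng.uniform(1.5, 3.0, 5)
        scores = np.concatenate([pos, neg])
        labels = np.array([True] * 20 + [False] * 5)
        roc = select_cutoff(roc_curve(scores, labels))
        assert neg.max() < roc.selected_cutoff < pos.min()
        assert roc.cutoff_sensitivity == 1.0
        assert roc.cutoff_specificity == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            select_cutoff(roc_curve(*FOUR_CASES), method="magic")

    def test_confusion_recount_matches_stored_operating_point(self):
        rng = np.random.default_rng(42)
        scores = np.round(rng.uniform(1, 5, 40), 1)
        labels = rng.random(40) < 0.7
        roc = select_cutoff(roc_curve(scores, labels))
        c = confusion_at(scores, labels, roc.selected_cutoff)
        assert c["sensitivity"] == pytest.approx(roc.cutoff_sensitivity)
        assert c["specificity"] == pytest.approx(roc.cutoff_specificity)


class TestConfusionAt:
    def test_threshold_below_all_scores(self):
        c = confusion_at([2.0, 3.0, 4.0], [True, False, True], 0.0)
        assert c["sensitivity"] == 1.0
        assert c["specificity"] == 0.0

    def test_threshold_above_all_scores(self):
        c = confusion_at([2.0, 3.0, 4.0], [True, False, True], 10.0)
        assert c["sensitivity"] == 0.0
        assert c["specificity"] == 1.0

    def test_hand_counted_example(self):
        c = confusion_at(*FOUR_CASES, threshold=3.25)
        assert (c["sensitivity"], c["specificity"]) == (1.0, 1.0)
        assert (c["tp"], c["fn"], c["tn"], c["fp"]) == (2, 0, 2, 0)


class TestGroupSummary:
    def test_identical_scores(self):
        g = group_summary([3, 3, 3], "A")
        assert (g.mean, g.sd) == (3.0, 0.0)

    def test_two_member_sample_sd(self):
        g = group_summary([2, 4], "B")
        assert g.mean == pytest.approx(3.0)
        assert g.sd == pytest.approx(np.sqrt(2))

    def test_single_member_group_has_no_sd(self):
        g = group_summary([4.2], "C")
        assert g.sd is None
        assert g.min == g.max == 4.2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_summary([], "A")


class TestSimulatedCohort:
    def test_default_cohort_is_well_discriminated(self):
        """At the modelled cohort statistics (88 vs 8, means 4.0/2.9, SD 0.4)
        the adequacy ROC is nearly perfect and Youden lands near 3.25."""
        scores, labels = simulate_score_cohort(seed=0)
        roc = select_cutoff(roc_curve(scores, labels))
        assert roc.auc > 0.95
        assert 3.0 < roc.selected_cutoff < 3.7
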