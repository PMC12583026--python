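import math

import numpy as np
import pandas as pd
import pytest

from cvtscreen.screening import (
    auc,
    auc_trapezoid,
    classify_orthostatic,
    confusion_at_cutoff,
    delong_ci,
    delong_variance,
    evaluate_biomarkers,
    is_reverse_dipper,
    roc_points,
    stage_can,
    youden_cutoff,
)

from reference import (
    reference_auc_paircount,
    reference_delong_variance,
    reference_youden,
)


class TestStageCAN:
    def test_no_abnormal(self):
        assert stage_can((False, False, False)) == "none"

    def test_one_abnormal(self):
        assert stage_can((True, False, False)) == "early"
        assert stage_can((False, False, True)) == "early"

    def test_two_or_more_abnormal(self):
        assert stage_can((True, True, False)) == "manifest"
        assert stage_can((True, True, True)) == "manifest"

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            stage_can((True, False))


class TestOrthostatic:
    def test_initial(self):
        assert classify_orthostatic((130, 80), [(0.5, 105, 78)]) == "initial"

    def test_delayed_diastolic(self):
        assert classify_orthostatic((130, 80), [(5, 125, 68)]) == "delayed"

    def test_none_below_threshold(self):
        assert classify_orthostatic((130, 80), [(2, 115, 72), (8, 116, 73)]) == "none"

    def test_classic_window(self):
        assert classify_orthostatic((130, 80), [(2.0, 105, 75)]) == "classic"

    def test_first_qualifying_reading_wins(self):
        readings = [(5, 100, 70), (0.5, 105, 78)]
        assert classify_orthostatic((130, 80), readings) == "initial"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_orthostatic((130, 80), [])

    def test_out_of_window_raises(self):
        with pytest.raises(ValueError):
            classify_orthostatic((130, 80), [(12, 100, 70)])


class TestReverseDipper:
    def test_systolic_rise(self):
        assert is_reverse_dipper((120, 80), (133, 78))

    def test_exact_ten_percent_boundary(self):
        assert is_reverse_dipper((120, 80), (132, 80))

    def test_below_threshold(self):
        assert not is_reverse_dipper((120, 80), (125, 82))

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            is_reverse_dipper((0, 80), (120, 80))


class TestROC:
    def test_perfect_separation(self):
        pts = roc_points([2, 3, 6, 7], [1, 1, 0, 0])
        assert any(p.fpr == 0.0 and p.tpr == 1.0 for p in pts)
        assert auc([2, 3, 6, 7], [1, 1, 0, 0]) == 1.0

    def test_identical_scores_auc_half(self):
        assert auc([5, 5, 5, 5], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_pair_count_example(self):
        scores, labels = [3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0]
        a = auc(scores, labels, lower_is_positive=False)
        assert a == pytest.approx(8.5 / 9)

    def test_monotone_points(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        pts = roc_points(scores, labels)
        fprs = [p.fpr for p in pts]
        tprs = [p.tpr for p in pts]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = np.concatenate([np.ones(15, bool), np.zeros(25, bool)])
        a1 = auc(scores, labels)
        a2 = auc(scores, ~labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_orientation_reversal(self, rng):
        scores = rng.normal(size=40)
        labels = np.concatenate([np.ones(15, bool), np.zeros(25, bool)])
        assert auc(scores, labels, True) + auc(scores, labels, False) == pytest.approx(1.0)

    def test_trapezoid_equals_pair_counting(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 9))
            n = int(rng.integers(1, 9))
            scores = np.concatenate(
                [rng.integers(0, 5, m), rng.integers(0, 5, n)]
            ).astype(float)
            labels = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            lower = bool(rng.integers(0, 2))
            a_rank = auc(scores, labels, lower)
            a_trap = auc_trapezoid(roc_points(scores, labels, lower))
            a_pair = reference_auc_paircount(scores, labels, lower)
            assert abs(a_rank - a_pair) < 1e-12
            assert abs(a_trap - a_pair) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        assert delong_variance([1, 2, 8, 9], [1, 1, 0, 0]) == pytest.approx(0.0)
        lo, hi = delong_ci([1, 2, 8, 9], [1, 1, 0, 0])
        assert (lo, hi) == (1.0, 1.0)

    def test_matches_brute_force_on_small_instances(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            scores = np.concatenate(
                [rng.integers(0, 6, m), rng.integers(0, 6, n)]
            ).astype(float)
            labels = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            lower = bool(rng.integers(0, 2))
            v = delong_variance(scores, labels, lower)
            v_ref = reference_delong_variance(scores, labels, lower)
            assert v == pytest.approx(v_ref, abs=1e-12)
            assert v >= 0.0

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(size=50)
        labels = np.concatenate([np.ones(20, bool), np.zeros(30, bool)])
        a = auc(scores, labels)
        lo, hi = delong_ci(scores, labels)
        assert lo <= a <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        widths = []
        for n_per in (20, 80, 320):
            w = []
            for _ in range(30):
                scores = np.concatenate([rng.normal(-0.7, 1, n_per), rng.normal(0, 1, n_per)])
                labels = np.concatenate([np.ones(n_per, bool), np.zeros(n_per, bool)])
                lo, hi = delong_ci(scores, labels)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]
        # rate ~ n^(-1/2): quadrupling n should roughly halve the width
        assert widths[1] / widths[0] == pytest.approx(0.5, abs=0.15)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            delong_variance([1, 5, 6], [1, 0, 0])


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff([2, 3, 6, 7], [1, 1, 0, 0])
        assert res.cutoff == 3.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_uninformative_marker(self):
        res = youden_cutoff([5, 5, 5, 5], [1, 1, 0, 0])
        assert res.sensitivity + res.specificity - 1.0 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(150):
            m = int(rng.integers(1, 7))
            n = int(rng.integers(1, 7))
            scores = np.concatenate(
                [rng.integers(0, 6, m), rng.integers(0, 6, n)]
            ).astype(float)
            labels = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            lower = bool(rng.integers(0, 2))
            res = youden_cutoff(scores, labels, lower)
            j = res.sensitivity + res.specificity - 1.0
            assert j == pytest.approx(reference_youden(scores, labels, lower), abs=1e-12)

    def test_tie_break_prefers_higher_specificity(self):
        # cutoffs 1 and 3 both give J=0.5; cutoff 1 has spec 1.0
        scores = [1.0, 3.0, 2.0, 4.0]
        labels = [1, 1, 0, 0]
        res = youden_cutoff(scores, labels)
        assert res.cutoff == 1.0
        assert res.specificity == 1.0
        assert set(res.tied_cutoffs) == {1.0, 3.0}


class TestConfusion:
    def test_perfect_classifier(self):
        c = confusion_at_cutoff([1, 2, 8, 9], [1, 1, 0, 0], cutoff=2.0)
        assert c == (1.0, 1.0, 0.0, 1.0, 1.0, 1.0)

    def test_hand_worked_table(self):
        # TP=5, FN=1, FP=7, TN=18 with lower-is-positive at cutoff 10
        scores = [5.0] * 5 + [15.0] * 1 + [5.0] * 7 + [15.0] * 18
        labels = [1] * 6 + [0] * 25
        c = confusion_at_cutoff(scores, labels, cutoff=10.0)
        assert c.sensitivity == pytest.approx(5 / 6)
        assert c.specificity == pytest.approx(18 / 25)
        assert c.ppv == pytest.approx(5 / 12)
        assert c.npv == pytest.approx(18 / 19)
        assert c.fpr == pytest.approx(1 - 18 / 25)
        assert c.tpr == c.sensitivity

    def test_all_predicted_negative(self):
        c = confusion_at_cutoff([5, 6, 7, 8], [1, 1, 0, 0], cutoff=1.0)
        assert math.isnan(c.ppv)
        assert c.npv == pytest.approx(0.5)


class TestEvaluateBiomarkers:
    @staticmethod
    def _frame(rng, n=40):
        stages = pd.Series(
            rng.choice(["none", "early", "manifest"], size=n, p=[0.5, 0.25, 0.25]),
            index=[f"S{i:03d}" for i in range(n)],
        )
        shift = stages.map({"none": 0.0, "early": -2.0, "manifest": -4.0})
        summaries = pd.DataFrame(
            {
                "short_term_mean": 6 + shift + rng.normal(0, 1, n),
                "long_term_mean": 8 + shift + rng.normal(0, 1, n),
                "long_term_capacity": 12 + shift + rng.normal(0, 2, n),
            },
            index=stages.index,
        )
        return summaries, stages

    def test_shape_and_outcomes(self, rng):
        summaries, stages = self._frame(rng)
        results = evaluate_biomarkers(summaries, stages)
        assert len(results) == 9
        assert {r.outcome for r in results} == {"any_can", "early_can", "manifest_can"}

    def test_early_contrast_excludes_manifest(self, rng):
        summaries, stages = self._frame(rng)
        results = evaluate_biomarkers(summaries, stages)
        early = [r for r in results if r.outcome == "early_can"][0]
        n_early = (stages == "early").sum()
        n_none = (stages == "none").sum()
        assert early.n_cases == n_early
        assert early.n_controls == n_none

    def test_pairwise_deletion(self, rng):
        summaries, stages = self._frame(rng)
        summaries.loc[summaries.index[:5], "short_term_mean"] = np.nan
        results = evaluate_biomarkers(summaries, stages)
        st_any = [r for r in results
                  if r.outcome == "any_can" and r.biomarker == "short_term_mean"][0]
        lt_any = [r for r in results
                  if r.outcome == "any_can" and r.biomarker == "long_term_mean"][0]
        assert st_any.n_cases + st_any.n_controls == len(stages) - 5
        assert lt_any.n_cases + lt_any.n_controls == len(stages)

    def test_few_cases_flagged_not_dropped(self, rng):
        stages = pd.Series(["none"] * 10 + ["manifest"], index=[f"S{i}" for i in range(11)])
        summaries = pd.DataFrame(
            {"short_term_mean": rng.normal(6, 1, 11),
             "long_term_mean": rng.normal(8, 1, 11),
             "long_term_capacity": rng.normal(12, 2, 11)},
            index=stages.index,
        )
        results = evaluate_biomarkers(summaries, stages, outcomes=("manifest_can",))
        assert all(not r.reliable for r in results)
        assert len(results) == 3

    def test_invariants(self, rng):
        summaries, stages = self._frame(rng)
        for r in evaluate_biomarkers(summaries, stages):
            assert 0.0 <= r.auc <= 1.0
            assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]
            assert r.fpr == pytest.approx(1.0 - r.specificity)
            assert r.tpr == pytest.approx(r.sensitivity)
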