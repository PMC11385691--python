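"""ROC/AUC, Youden thresholds, confusion metrics and consensus rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_best_j, manual_confusion, pairwise_auc
from sbtkin import (
    STANDARD_GROUPINGS,
    ConsensusRule,
    LabeledScores,
    confusion_metrics,
    consensus_diagnose,
    consensus_rule_battery,
    evaluate_grouping,
    optimal_threshold,
    roc_and_auc,
    table1_layout,
)
from sbtkin.evaluate import UndefinedRocError


def scores(pos, neg, orientation=+1):
    s = np.concatenate([pos, neg]).astype(float)
    y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledScores(ids=tuple(range(s.size)), scores=s, labels=y,
                         orientation=orientation)


class TestRocAndAuc:
    def test_perfect_separation(self):
        assert roc_and_auc(scores([5, 6, 7], [1, 2, 3])).auc == pytest.approx(1.0)

    def test_all_tied_scores_are_chance(self):
        assert roc_and_auc(scores([2, 2], [2, 2, 2])).auc == pytest.approx(0.5)

    def test_worked_pair_example(self):
        # positives {3, 1}, negatives {2, 0}: 3 of 4 pairs concordant
        assert roc_and_auc(scores([3, 1], [2, 0])).auc == pytest.approx(0.75)

    def test_matches_pair_statistic_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(60):
            npos, nneg = rng.integers(1, 9, size=2)
            pool = rng.integers(0, 6, size=npos + nneg).astype(float)
            data = scores(pool[:npos], pool[npos:])
            expected = pairwise_auc(pool[:npos], pool[npos:])
            assert abs(roc_and_auc(data).auc - expected) < 1e-12

    def test_orientation_antisymmetry(self):
        rng = np.random.default_rng(21)
        vals = rng.permutation(12).astype(float)  # tie-free
        y = rng.integers(0, 2, 12)
        y[:2] = [0, 1]
        a = LabeledScores(tuple(range(12)), vals, y, +1)
        b = LabeledScores(tuple(range(12)), vals, y, -1)
        assert roc_and_auc(a).auc + roc_and_auc(b).auc == pytest.approx(1.0)

    def test_curve_is_monotone_with_unit_endpoints(self):
        rr = roc_and_auc(scores([3, 1, 4], [2, 0, 2]))
        assert np.all(np.diff(rr.tpr) >= 0) and np.all(np.diff(rr.fpr) >= 0)
        assert rr.fpr[0] == rr.tpr[0] == 0.0
        assert rr.fpr[-1] == rr.tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRocError):
            roc_and_auc(scores([1, 2], []))


class TestOptimalThreshold:
    def test_perfect_separation_gives_unit_j(self):
        res = optimal_threshold(scores([5, 6], [1, 2]))
        assert res.youden_j == pytest.approx(1.0)
        assert res.metrics.sensitivity == res.metrics.specificity == 1.0
        assert 2 < res.threshold < 5

    def test_worked_example_max_j(self):
        res = optimal_threshold(scores([3, 1], [2, 0]))
        assert res.youden_j == pytest.approx(0.5)
        assert res.metrics.specificity == pytest.approx(1.0)  # tie-break

    def test_single_swap_breaks_perfection(self):
        res = optimal_threshold(scores([5, 2], [1, 4]))
        assert res.youden_j < 1.0

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            npos, nneg = rng.integers(2, 8, size=2)
            pool = rng.normal(size=npos + nneg)
            data = scores(pool[:npos], pool[npos:])
            res = optimal_threshold(data)
            assert res.youden_j == pytest.approx(
                exhaustive_best_j(data.oriented(), data.labels), abs=1e-12
            )

    def test_predict_respects_orientation(self):
        data = scores([0.5, 0.2], [2.0, 3.0], orientation=-1)  # low = positive
        res = optimal_threshold(data)
        np.testing.assert_array_equal(res.predict([0.1, 5.0]), [1, 0])


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert m.accuracy == m.sensitivity == m.specificity == m.mcc == 1.0

    def test_inverted_prediction(self):
        m = confusion_metrics([0, 1, 0], [1, 0, 1])
        assert m.mcc == pytest.approx(-1.0)

    def test_worked_counts_example(self):
        # tp=8, fn=0, tn=6, fp=2
        labels = [1] * 8 + [0] * 8
        preds = [1] * 8 + [1, 1] + [0] * 6
        m = confusion_metrics(preds, labels)
        assert (m.tp, m.fp, m.tn, m.fn) == (8, 2, 6, 0)
        assert m.accuracy == pytest.approx(0.875)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.specificity == pytest.approx(0.75)
        assert m.mcc == pytest.approx(48 / np.sqrt(3840))

    def test_constant_predictions_have_zero_mcc(self):
        assert confusion_metrics([1, 1, 1], [0, 1, 0]).mcc == 0.0
        assert confusion_metrics([0, 0, 0], [0, 1, 0]).mcc == 0.0

    def test_matches_manual_computation_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = rng.integers(2, 30)
            pred = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            m = confusion_metrics(pred, y)
            ref = manual_confusion(pred, y)
            assert (m.tp, m.fp, m.tn, m.fn) == (
                ref["tp"], ref["fp"], ref["tn"], ref["fn"],
            )
            assert m.accuracy == ref["accuracy"]
            assert m.mcc == pytest.approx(ref["mcc"], abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


class TestConsensusDiagnose:
    def test_truth_table_row(self):
        calls = np.array([[1, 1, 0]])
        assert consensus_diagnose(calls, ConsensusRule("and", (0, 1)))[0] == 1
        assert consensus_diagnose(calls, ConsensusRule("and", (0, 1, 2)))[0] == 0
        assert consensus_diagnose(calls, ConsensusRule("or", (0, 1, 2)))[0] == 1
        assert consensus_diagnose(calls, ConsensusRule("majority"))[0] == 1

    def test_all_negative_row(self):
        calls = np.zeros((1, 3), dtype=int)
        for rule in (
            ConsensusRule("single", (1,)),
            ConsensusRule("and", (0, 2)),
            ConsensusRule("or", (0, 1, 2)),
            ConsensusRule("majority"),
        ):
            assert consensus_diagnose(calls, rule)[0] == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**12 - 1))
    def test_logical_monotonicity(self, bits):
        calls = np.array([int(b) for b in f"{bits:012b}"]).reshape(4, 3)
        land = consensus_diagnose(calls, ConsensusRule("and", (0, 1, 2)))
        lor = consensus_diagnose(calls, ConsensusRule("or", (0, 1, 2)))
        for k in range(3):
            single = consensus_diagnose(calls, ConsensusRule("single", (k,)))
            assert np.all(land <= single) and np.all(single <= lor)

    def test_majority_requires_three(self):
        with pytest.raises(ValueError):
            consensus_diagnose(np.zeros((2, 2), int), ConsensusRule("majority"))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            consensus_diagnose(np.zeros((2, 3), int), ConsensusRule("and", ()))

    def test_or_sensitivity_and_and_specificity_bounds(self):
        """Union can only gain sensitivity; intersection only specificity."""
        rng = np.random.default_rng(24)
        for _ in range(30):
            n = 20
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            calls = rng.integers(0, 2, (n, 3))
            sens = [confusion_metrics(calls[:, k], y).sensitivity for k in range(3)]
            spec = [confusion_metrics(calls[:, k], y).specificity for k in range(3)]
            m_or = confusion_metrics(
                consensus_diagnose(calls, ConsensusRule("or", (0, 1, 2))), y
            )
            m_and = confusion_metrics(
                consensus_diagnose(calls, ConsensusRule("and", (0, 1, 2))), y
            )
            assert m_or.sensitivity >= max(sens) - 1e-12
            assert m_and.specificity >= max(spec) - 1e-12


class TestBatteryAndGrouping:
    def test_battery_size_for_three_classifiers(self):
        battery = consensus_rule_battery(["rho", "cpdr90", "t50"])
        assert len(battery) == 12  # 3 singles + 3&3 pairs + both triples + majority

    def test_report_layout_has_eleven_columns(self):
        layout = table1_layout(["rho", "cpdr90", "t50"])
        assert len(layout) == 11
        assert "rho & cpdr90 & t50" not in layout
        assert "rho | cpdr90 | t50" in layout

    def _toy_table(self):
        rng = np.random.default_rng(25)
        rows = []
        for i in range(10):
            for cond, shift in (("0", 0.0), ("100", -1.0), ("750", -3.0)):
                rows.append(
                    {
                        "participant_id": f"P{i}",
                        "condition": cond,
                        "duration_min": 240,
                        "rho": 1.3 + shift * 0.3 + rng.normal(0, 0.1),
                        "cpdr90": 20 + shift * 4 + rng.normal(0, 1),
                        "t50": 2.0 - shift * 0.5 + rng.normal(0, 0.2),
                    }
                )
        return pd.DataFrame(rows)

    def test_evaluate_grouping_structure(self):
        table = self._toy_table()
        res = evaluate_grouping(
            table, STANDARD_GROUPINGS[1], ("rho", "cpdr90", "t50"), duration=240
        )
        assert set(res["roc"]) == {"rho", "cpdr90", "t50"}
        assert len(res["metrics"]) == 12
        assert res["metrics"]["mcc"].between(-1, 1).all()
        # strong synthetic separation: severe grouping should be near-perfect
        assert res["roc"]["cpdr90"].auc > 0.95

    def test_missing_classifier_column_raises(self):
        with pytest.raises(KeyError):
            evaluate_grouping(
                self._toy_table(), STANDARD_GROUPINGS[0], ("rho", "tpeak"), 240
            )
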