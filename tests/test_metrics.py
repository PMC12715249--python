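"""Evaluation framework: printed-table fixtures, oracle equivalence,
metric identities, ranking."""

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics as skm

from coronal_caps.metrics import (LABEL_CODING, aggregate_metrics, auc_metrics,
                                  balanced_accuracy, bias_index, confusion_matrix,
                                  degenerate_predictions, evaluate, mcc,
                                  ordinal_mse, per_class_metrics, rank_models,
                                  round_half_away)

# the study's printed test-set composition: 447 CN / 677 MCI / 859 AD
TEST_COUNTS = {"CN": 447, "MCI": 677, "AD": 859}


@pytest.fixture(scope="module")
def all_ad():
    return degenerate_predictions(TEST_COUNTS, "AD")


@pytest.fixture(scope="module")
def all_mci():
    return degenerate_predictions(TEST_COUNTS, "MCI")


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([2, 2, 1]))

    def test_all_ad_third_column(self, all_ad):
        true, pred, _ = all_ad
        cm = confusion_matrix(true, pred)
        assert cm[:, 2].tolist() == [447, 677, 859]
        assert cm[:, :2].sum() == 0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_matrix([], [])

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="unknown label"):
            confusion_matrix(["CN", "XX"], ["CN", "CN"])


class TestDegenerateRows:
    """The single-class predictor rows of the printed metric tables."""

    def test_all_ad_per_class_row(self, all_ad):
        true, pred, _ = all_ad
        per = per_class_metrics(confusion_matrix(true, pred))
        assert round_half_away(100 * per.loc["AD", "precision"]) == 43
        assert per.loc["AD", "sensitivity"] == 1.0
        assert round_half_away(100 * per.loc["AD", "f1"]) == 60
        # never-predicted classes: 0/0 -> 0 convention
        for cls in ("CN", "MCI"):
            assert per.loc[cls, "precision"] == 0.0
            assert per.loc[cls, "sensitivity"] == 0.0
            assert per.loc[cls, "f1"] == 0.0
        assert per["support"].tolist() == [447, 677, 859]

    def test_all_ad_aggregates(self, all_ad):
        true, pred, _ = all_ad
        agg = aggregate_metrics(confusion_matrix(true, pred))
        assert round_half_away(100 * agg["accuracy"]) == 43
        assert round_half_away(100 * agg["macro_precision"]) == 14
        assert round_half_away(100 * agg["macro_sensitivity"]) == 33
        assert round_half_away(100 * agg["macro_specificity"]) == 67
        assert round_half_away(100 * agg["macro_f1"]) == 20

    def test_all_ad_balanced_accuracy_50(self, all_ad):
        true, pred, _ = all_ad
        assert round_half_away(100 * balanced_accuracy(confusion_matrix(true, pred))) == 50

    def test_ordinal_mse_124_and_66(self, all_ad, all_mci):
        # (447*4 + 677*1)/1983 * 100 = 124.3; (447 + 859)/1983 * 100 = 65.9
        assert round_half_away(ordinal_mse(all_ad[0], all_ad[1])) == 124
        assert round_half_away(ordinal_mse(all_mci[0], all_mci[1])) == 66

    def test_perfect_predictions_mse_zero(self):
        y = np.array([0, 1, 2])
        assert ordinal_mse(y, y) == 0.0

    def test_all_ad_roc_aucs(self, all_ad):
        true, _, scores = all_ad
        auc = auc_metrics(scores, true)
        assert round_half_away(100 * auc["roc_auc_micro"]) == 57
        assert auc["roc_auc_macro"] == pytest.approx(0.5)

    def test_all_mci_reproduces_second_degenerate_row(self, all_mci):
        true, pred, _ = all_mci
        per = per_class_metrics(confusion_matrix(true, pred))
        assert round_half_away(100 * per.loc["MCI", "precision"]) == 34
        assert per.loc["MCI", "sensitivity"] == 1.0
        assert round_half_away(100 * per.loc["MCI", "f1"]) == 51  # 0.5097

    def test_single_class_predictor_bias_index_one(self, all_ad, all_mci):
        for true, pred, _ in (all_ad, all_mci):
            pred_dist = np.bincount(pred, minlength=3) / len(pred)
            true_dist = np.bincount(true, minlength=3) / len(true)
            assert bias_index(pred_dist, true_dist) == pytest.approx(1.0)

    def test_tiny_degenerate_counts(self):
        true, pred, _ = degenerate_predictions({"CN": 1, "MCI": 1, "AD": 1}, "CN")
        agg = aggregate_metrics(confusion_matrix(true, pred))
        assert agg["accuracy"] == pytest.approx(1 / 3)


class TestOracleEquivalence:
    """Every metric must agree with explicit TP/FP/FN/TN loops on random
    confusion matrices."""

    @staticmethod
    def brute_force(cm):
        n = cm.sum()
        out = {"accuracy": sum(cm[k, k] for k in range(3)) / n}
        prec, sens, spec, f1 = [], [], [], []
        for k in range(3):
            tp = cm[k, k]
            fn = sum(cm[k, j] for j in range(3)) - tp
            fp = sum(cm[i, k] for i in range(3)) - tp
            tn = n - tp - fn - fp
            p = tp / (tp + fp) if tp + fp else 0.0
            s = tp / (tp + fn) if tp + fn else 0.0
            prec.append(p)
            sens.append(s)
            spec.append(tn / (tn + fp) if tn + fp else 0.0)
            f1.append(2 * p * s / (p + s) if p + s else 0.0)
        out["macro_precision"] = sum(prec) / 3
        out["macro_sensitivity"] = sum(sens) / 3
        out["macro_specificity"] = sum(spec) / 3
        out["macro_f1"] = sum(f1) / 3
        supports = [sum(cm[k, j] for j in range(3)) for k in range(3)]
        out["weighted_f1"] = sum(f * s for f, s in zip(f1, supports)) / n
        out["balanced_accuracy"] = (out["macro_sensitivity"]
                                    + out["macro_specificity"]) / 2
        return out

    def test_agrees_on_1000_random_cms(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cm = rng.integers(0, 30, (3, 3))
            if cm.sum() == 0:
                cm[0, 0] = 1
            agg = aggregate_metrics(cm)
            ref = self.brute_force(cm)
            for key, val in ref.items():
                if key == "balanced_accuracy":
                    assert balanced_accuracy(cm) == pytest.approx(val)
                else:
                    assert agg[key] == pytest.approx(val), key

    def test_mcc_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 3, 60)
            p = rng.integers(0, 3, 60)
            assert mcc(confusion_matrix(t, p)) == pytest.approx(
                skm.matthews_corrcoef(t, p), abs=1e-12)

    def test_aucs_match_sklearn_on_random_scores(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, 200)
        S = rng.dirichlet(np.ones(3), 200)
        auc = auc_metrics(S, t)
        onehot = np.eye(3)[t]
        assert auc["roc_auc_macro"] == pytest.approx(
            skm.roc_auc_score(t, S, multi_class="ovr", average="macro"))
        assert auc["roc_auc_micro"] == pytest.approx(
            skm.roc_auc_score(onehot.ravel(), S.ravel()))


class TestIdentities:
    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            cm = rng.integers(0, 25, (3, 3))
            if cm.sum() == 0:
                continue
            agg = aggregate_metrics(cm)
            assert agg["weighted_sensitivity"] == pytest.approx(agg["accuracy"])

    def test_perfect_scores_all_aucs_one(self):
        t = np.array([0, 1, 2] * 10)
        S = np.eye(3)[t] * 0.98 + 0.01
        auc = auc_metrics(S, t)
        assert auc["roc_auc_macro"] == 1.0
        assert auc["mcc"] == pytest.approx(1.0)

    def test_random_scores_macro_auc_near_half(self):
        rng = np.random.default_rng(4)
        n = 10_000
        t = rng.integers(0, 3, n)
        S = rng.dirichlet(np.ones(3), n)
        auc = auc_metrics(S, t)
        assert 0.49 < auc["roc_auc_macro"] < 0.51

    def test_single_class_truth_auc_half_by_convention(self):
        t = np.zeros(10, dtype=int)
        S = np.tile([0.6, 0.3, 0.1], (10, 1))
        assert auc_metrics(S, t)["roc_auc_macro"] == pytest.approx(0.5)


class TestBiasIndex:
    def test_matched_distribution_zero(self):
        p = np.array([0.225, 0.342, 0.433])
        assert bias_index(p, p) == 0.0

    def test_uniform_prediction_strictly_between(self):
        val = bias_index(np.full(3, 1 / 3), np.array([0.225, 0.342, 0.433]))
        assert 0.0 < val < 1.0

    def test_custom_formula_hook(self):
        val = bias_index(np.array([1, 0, 0]), np.array([0.5, 0.3, 0.2]),
                         formula=lambda a, b: float(np.max(np.abs(a - b))))
        assert val == pytest.approx(0.5)


class TestRanking:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["model", "top1", "top5",
                                           "param_count", "performance_score"])

    def test_single_row(self):
        out = rank_models(self._table([("m", 50.0, 80.0, 10.0, 0.5)]))
        assert out["rank"].tolist() == [1]
        # constant columns normalize to 0 by convention
        assert out["top1_norm"].tolist() == [0.0]

    def test_tie_broken_by_param_count(self):
        out = rank_models(self._table([
            ("big", 50.0, 80.0, 100.0, 0.5),
            ("small", 50.0, 80.0, 10.0, 0.5),
        ]))
        assert out.iloc[0]["model"] == "small"

    def test_five_row_hand_sorted_oracle(self):
        rows = [("a", 40, 70, 30, 0.3), ("b", 55, 85, 50, 0.7),
                ("c", 52, 85, 20, 0.7), ("d", 60, 90, 80, 0.9),
                ("e", 45, 75, 40, 0.4)]
        out = rank_models(self._table(rows))
        # hand sort: d (0.9), then b/c tied 0.7 with equal top5 -> smaller
        # params (c) first, then e, then a
        assert out["model"].tolist() == ["d", "c", "b", "e", "a"]

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_models(pd.DataFrame())


class TestReport:
    def test_full_report_roundtrip(self, all_ad):
        true, pred, scores = all_ad
        rep = evaluate(true, pred, scores)
        summary = rep.summary_percent()
        assert summary["accuracy"] == 43
        assert summary["balanced_accuracy"] == 50
        assert summary["mse_percent"] == 124
        assert summary["roc_auc_micro"] == 57
        assert rep.bias_index == pytest.approx(1.0)

    def test_rounding_convention_half_away(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(1.5) == 2
        assert round_half_away(-0.5) == -1
        assert round_half_away(2.4) == 2
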